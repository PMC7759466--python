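"""Novel- and rare-variant accounting.

A variant is *novel* when absent from every supplied catalogue, except for
the technical-artefact class: sites fixed derived in all populations whose
derived allele is the reference allele (these usually reflect a wrong
ancestral call, not new variation).  Per-individual counts, discovery
saturation curves, singleton sharing and effect-stratified site frequency
spectra all operate on derived-allele polarization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, GenotypeMatrix, PopulationManifest, SiteTable
from .frequencies import derived_counts

logger = logging.getLogger(__name__)


def flag_novel(
    sites: SiteTable, catalogues: list[str], pop_dafs: pd.DataFrame
) -> np.ndarray:
    """Boolean novelty flag per site.

    ``catalogues`` are catalogue names checked against each site's
    ``catalogue_flags``; ``pop_dafs`` is the sites x populations DAF table
    used for the fixed-derived-reference artefact exclusion.
    """
    in_any = np.array(
        [bool(flags & set(catalogues)) for flags in sites.df["catalogue_flags"]]
    )
    daf = pop_dafs.to_numpy()
    with np.errstate(invalid="ignore"):
        fixed_everywhere = np.all(np.nan_to_num(daf, nan=1.0) >= 1.0, axis=1) & np.any(
            ~np.isnan(daf), axis=1
        )
    derived_is_ref = sites.ancestral_is_alt  # ancestral = alt => derived = ref
    artefact = fixed_everywhere & derived_is_ref
    return ~in_any & ~artefact


def per_individual_novel_counts(
    geno: GenotypeMatrix,
    novel_flags: np.ndarray,
    manifest: PopulationManifest,
    subsample_n: int = 24,
    seed: int = 0,
) -> pd.Series:
    """Novel-site carrier counts for a seeded subsample per population.

    An individual counts a novel site when carrying at least one derived
    allele there (carrier status, not dosage).
    """
    rng = np.random.default_rng(seed)
    novel_flags = np.asarray(novel_flags, dtype=bool)
    flip = geno.sites.ancestral_is_alt
    counts: dict[str, int] = {}
    for pop in manifest.population_ids:
        members = manifest.members(pop)
        if len(members) < subsample_n:
            raise ValueError(
                f"population {pop!r} has {len(members)} members < {subsample_n}"
            )
        chosen = rng.choice(members, size=subsample_n, replace=False)
        idx = geno.sample_index(chosen)
        calls = geno.calls[np.ix_(novel_flags, idx)]
        derived = np.where(
            flip[novel_flags, None], 2 - calls, calls
        )  # MISSING (-1) maps to 3 when flipped; mask both codes
        carrier = (derived >= 1) & (calls != MISSING) & (derived <= 2)
        for s, c in zip(chosen, carrier.sum(axis=0)):
            counts[s] = int(c)
    return pd.Series(counts, name="novel_count")


def novel_sets_per_population(
    novel_flags: np.ndarray, pop_dafs: pd.DataFrame, common_only: bool = False,
    pop_allele_counts: pd.DataFrame | None = None,
) -> dict[str, set[int]]:
    """Site-index sets of novel variants observed (DAF > 0) per population.

    With ``common_only``, sites observed exactly once in the population
    (derived allele count 1) are excluded; requires ``pop_allele_counts``
    (derived count per site per population).
    """
    out = {}
    for pop in pop_dafs.columns:
        seen = (pop_dafs[pop].to_numpy() > 0) & np.asarray(novel_flags, dtype=bool)
        if common_only:
            if pop_allele_counts is None:
                raise ValueError("common_only requires pop_allele_counts")
            seen &= pop_allele_counts[pop].to_numpy() > 1
        out[pop] = set(np.flatnonzero(seen))
    return out


def cumulative_discovery(
    novel_sets: dict[str, set[int]], order: list[str]
) -> pd.DataFrame:
    """Cumulative union-size curve over a population ordering."""
    unknown = [p for p in order if p not in novel_sets]
    if unknown:
        raise ValueError(f"unknown population(s) in order: {unknown}")
    seen: set[int] = set()
    rows = []
    for pop in order:
        seen |= novel_sets[pop]
        rows.append((pop, len(seen)))
    return pd.DataFrame(rows, columns=["population", "cumulative_novel"])


def singleton_sharing(
    pop_allele_counts: pd.DataFrame, pop_dafs: pd.DataFrame
) -> pd.Series:
    """Per population: fraction of its singleton sites seen elsewhere.

    A singleton has derived allele count exactly 1 within the population;
    it is shared when any other population has DAF > 0 at the site.
    """
    pops = list(pop_allele_counts.columns)
    out = {}
    for pop in pops:
        single = pop_allele_counts[pop].to_numpy() == 1
        others = [p for p in pops if p != pop]
        elsewhere = (pop_dafs[others].to_numpy() > 0).any(axis=1)
        n_single = int(single.sum())
        out[pop] = float((single & elsewhere).sum() / n_single) if n_single else np.nan
    return pd.Series(out, name="singleton_shared_fraction")


def sfs_by_effect(
    geno: GenotypeMatrix,
    sites: SiteTable,
    manifest: PopulationManifest,
    population: str,
    subsample_n: int = 24,
    rare_daf_max: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Relative SFS per effect class in a subsample of ``subsample_n``
    diploids (derived counts 1 .. 2n-1), plus rare flags (DAF <= threshold).

    Sites with missing calls in the subsample are down-projected by
    recomputing the count over called alleles scaled to 2n (rounded), the
    standard small-sample projection.
    """
    rng = np.random.default_rng(seed)
    members = manifest.members(population)
    if len(members) < subsample_n:
        raise ValueError(f"population {population!r} smaller than {subsample_n}")
    chosen = list(rng.choice(members, size=subsample_n, replace=False))
    derived, n_alleles = derived_counts(geno, sites, chosen)
    n_max = 2 * subsample_n
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(
            n_alleles > 0, np.rint(derived / n_alleles * n_max), np.nan
        )
    daf_full, n_full = derived_counts(geno, sites, manifest.members(population))
    with np.errstate(invalid="ignore", divide="ignore"):
        rare = (daf_full / np.maximum(n_full, 1)) <= rare_daf_max

    classes = [c for c in sites.df["effect_class"].unique() if c is not None]
    spectra = {}
    bins = np.arange(1, n_max)
    for cls in sorted(classes):
        mask = (sites.df["effect_class"] == cls).to_numpy()
        counts = scaled[mask]
        counts = counts[~np.isnan(counts)]
        counts = counts[(counts >= 1) & (counts <= n_max - 1)]
        if counts.size == 0:
            logger.warning("effect class %s has no segregating sites", cls)
            spectra[cls] = np.zeros(len(bins))
            continue
        hist = np.histogram(counts, bins=np.arange(0.5, n_max, 1.0))[0]
        spectra[cls] = hist / hist.sum()
    sfs = pd.DataFrame(spectra, index=pd.Index(bins, name="derived_count"))
    return sfs, np.nan_to_num(rare, nan=False).astype(bool)


def ancestry_novelty_correlation(
    novel_counts: pd.Series, ancestry: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between per-individual novel counts and an
    ancestry proportion, with its two-sided t-distribution P value."""
    joined = pd.concat([novel_counts, ancestry], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 individuals")
    x, y = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in counts or ancestry")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
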