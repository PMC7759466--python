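"""Core in-memory containers for a multi-population WGS cohort.

All downstream statistics are polarized by ancestral state (derived vs
ancestral allele) rather than by reference vs alternative, to avoid the
reference-genome construction bias.  Coordinates follow the conventions of
the source formats: VCF positions are 1-based; all window/interval outputs
are 0-based half-open (BED).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EFFECT_CLASSES = ("pLOF", "missense", "synonymous", "noncoding", "other")
CLINICAL_CLASSES = ("pathogenic", "likely_pathogenic", "VUS", "other")

MISSING = -1  # missing genotype sentinel in GenotypeMatrix.calls

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SiteTable:
    """Per-variant annotation table.

    ``df`` columns: chrom (str), pos (int, 1-based), ref, alt (single base),
    ancestral (single base or ``"."`` for unknown), gene_id (str or None),
    effect_class (one of :data:`EFFECT_CLASSES` or None), catalogue_flags
    (frozenset of catalogue names), clinical_class (one of
    :data:`CLINICAL_CLASSES` or None), region_labels (frozenset).
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "pos", "ref", "alt", "ancestral")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"SiteTable missing column {col!r}")
        for col, default in (
            ("gene_id", None),
            ("effect_class", None),
            ("clinical_class", None),
        ):
            if col not in self.df.columns:
                self.df[col] = default
        for col in ("catalogue_flags", "region_labels"):
            if col not in self.df.columns:
                self.df[col] = [frozenset()] * len(self.df)
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if (df["ref"] == df["alt"]).any():
            raise ValueError("ref == alt at some site")
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        bad = ~(
            (df["ancestral"] == df["ref"])
            | (df["ancestral"] == df["alt"])
            | (df["ancestral"] == ".")
        )
        if bad.any():
            raise ValueError("ancestral allele must be ref, alt or '.'")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def ancestral_known(self) -> np.ndarray:
        return (self.df["ancestral"] != ".").to_numpy()

    @property
    def ancestral_is_alt(self) -> np.ndarray:
        """True where the ALT allele is ancestral (so REF is derived)."""
        return (self.df["ancestral"] == self.df["alt"]).to_numpy()

    @property
    def is_ambiguous(self) -> np.ndarray:
        """Strand-ambiguous A/T or C/G SNVs."""
        pairs = list(zip(self.df["ref"], self.df["alt"]))
        return np.array([p in _AMBIGUOUS_PAIRS for p in pairs])

    def in_region(self, label: str) -> np.ndarray:
        return np.array([label in r for r in self.df["region_labels"]])

    def subset(self, mask: np.ndarray) -> "SiteTable":
        return SiteTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Diploid ALT-allele dosages, sites x samples.

    ``calls[i, j]`` is the number of ALT alleles carried by sample ``j`` at
    site ``i``: 0, 1, 2 or :data:`MISSING` (-1).
    """

    sites: SiteTable
    samples: list[str]
    calls: np.ndarray
    sex: np.ndarray | None = None  # per-sample: 'male' / 'female' / 'unknown'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sites)}, {len(self.samples)})"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")
        if self.sex is None:
            self.sex = np.array(["unknown"] * len(self.samples))
        self.sex = np.asarray(self.sex)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix")

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.sites.subset(mask), list(self.samples), self.calls[mask], self.sex
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            self.sites, [self.samples[i] for i in idx], self.calls[:, idx],
            self.sex[idx],
        )

    def alt_frequency(self) -> np.ndarray:
        """ALT allele frequency per site over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=1)
        alt = np.where(obs, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes polarized as 0 = ancestral, 1 = derived.

    ``haps`` has shape (2 * n_samples, n_sites); haplotypes ``2j`` and
    ``2j + 1`` belong to diploid sample ``j``.  ``genetic_pos`` is the map
    position of each site in centimorgans, non-decreasing.
    """

    haps: np.ndarray
    samples: list[str]
    genetic_pos: np.ndarray
    positions: np.ndarray  # bp, 1-based, mirrors the SiteTable

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haps.shape[0] != 2 * len(self.samples):
            raise ValueError("need exactly two haplotypes per sample")
        if self.haps.shape[1] != len(self.genetic_pos):
            raise ValueError("genetic map length mismatch")
        if np.any(np.diff(self.genetic_pos) < 0):
            raise ValueError("genetic positions must be non-decreasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def haplotypes_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        rows = []
        for s in sample_ids:
            j = lookup[s]
            rows.extend((2 * j, 2 * j + 1))
        return self.haps[rows]

    def derived_frequency(self) -> np.ndarray:
        return self.haps.mean(axis=0)


@dataclass
class PopulationManifest:
    """Population metadata: membership, geography, ancestry, mortality.

    ``samples``: DataFrame indexed by sample id with columns ``population``,
    ``sex``, ``affected`` (frozenset of exclusion labels) and one
    ``anc_<component>`` column per ancestry component (fractions summing
    to 1 per sample).
    ``populations``: DataFrame indexed by population id with ``lat``, ``lon``
    and one ``mortality_<disease>`` column per disease (deaths per 100,000).
    """

    samples: pd.DataFrame
    populations: pd.DataFrame

    def __post_init__(self) -> None:
        if "population" not in self.samples.columns:
            raise ValueError("manifest samples need a 'population' column")
        if "affected" not in self.samples.columns:
            self.samples["affected"] = [frozenset()] * len(self.samples)
        if "sex" not in self.samples.columns:
            self.samples["sex"] = "unknown"
        unknown = set(self.samples["population"]) - set(self.populations.index)
        if unknown:
            raise ValueError(f"populations missing from manifest: {sorted(unknown)}")
        anc = self.ancestry_columns
        if anc:
            tot = self.samples[anc].sum(axis=1).to_numpy()
            if np.any(np.abs(tot - 1.0) > 1e-6):
                raise ValueError("ancestry proportions must sum to 1 per sample")

    @property
    def ancestry_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("anc_")]

    @property
    def population_ids(self) -> list[str]:
        return list(self.populations.index)

    def members(self, population: str) -> list[str]:
        if population not in self.populations.index:
            raise KeyError(f"unknown population {population!r}")
        sub = self.samples[self.samples["population"] == population]
        return list(sub.index)

    def population_of(self, sample: str) -> str:
        return self.samples.loc[sample, "population"]

    def mortality(self, disease: str) -> pd.Series:
        col = f"mortality_{disease}"
        if col not in self.populations.columns:
            raise KeyError(f"no mortality rates for disease {disease!r}")
        return self.populations[col]

    def coordinates(self) -> pd.DataFrame:
        return self.populations[["lat", "lon"]]


@dataclass
class WindowScoreTrack:
    """Per-window genome scan scores for one population.

    Windows are fixed width, non-overlapping, 0-based half-open.
    """

    population: str
    df: pd.DataFrame  # chrom, start, end, score, n_snvs, outlier

    COLUMNS = ("chrom", "start", "end", "score", "n_snvs", "outlier")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"track missing column {col!r}")
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            if np.any(end <= start):
                raise ValueError("empty or inverted window")
            order = np.argsort(start)
            if np.any(end[order][:-1] > start[order][1:]):
                raise ValueError("overlapping windows in track")
        if (self.df["n_snvs"] < 0).any():
            raise ValueError("negative n_snvs")

    def __len__(self) -> int:
        return len(self.df)


def window_of(pos: np.ndarray, width: int = 10_000) -> np.ndarray:
    """0-based half-open window start for 1-based positions ``pos``."""
    return ((np.asarray(pos) - 1) // width) * width
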