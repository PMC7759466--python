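"""Synthetic multi-population cohorts with the structure the scans assume.

Allele frequencies follow the Balding-Nichols model: an ancestral frequency
``p ~ Uniform(0.02, 0.98)`` per site and, for each ancestry component with
drift parameter ``F``, a component frequency ``~ Beta(p(1-F)/F, (1-p)(1-F)/F)``.
Admixed populations mix component frequencies linearly.  Haplotypes are
mosaics of per-population founder haplotypes (copying with a per-site switch
probability), which creates linkage disequilibrium without a coalescent
simulation.  A selective sweep is planted as a star-like event: a fraction of
haplotypes is overwritten by a single founder around a core position, with a
per-site escape probability ``1 - exp(-d / decay_scale)`` at map distance
``d`` restoring the original allele.

Mortality rates per population are generated as a noisy linear function of
the true loss-of-function burden ratio, so the burden-mortality test has a
recoverable signal whose strength is controlled by ``mortality_noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationManifest,
    SiteTable,
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SweepSpec:
    population: str = "P1"
    core_pos: int | None = None  # bp; defaults to mid-chromosome
    carrier_fraction: float = 0.85
    decay_scale_cM: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_fraction < 1.0):
            raise ValueError("carrier_fraction must be in (0, 1)")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the shape of a continental WGS survey at desk scale:
    six populations spanning drift F = 0.02-0.2, one of them admixed, 30
    diploid samples per population, and a single chromosome with a constant
    1 cM/Mb map.
    """

    n_populations: int = 6
    samples_per_pop: int = 30
    n_sites: int = 12000
    chrom_length_bp: int = 4_000_000
    chrom: str = "1"
    fst: tuple[float, ...] = (0.02, 0.05, 0.08, 0.10, 0.15, 0.20)
    # pop x component mixing weights; None = identity except the last
    # population, which is a 50/50 mix of the first two components.
    admixture: np.ndarray | None = None
    sweep: SweepSpec | None = field(default_factory=SweepSpec)
    n_founders: int = 100
    switch_rate: float = 0.05  # founder-mosaic per-site switch probability
    cm_per_mb: float = 1.0
    effect_probs: dict = field(
        default_factory=lambda: {
            "pLOF": 0.02,
            "missense": 0.23,
            "synonymous": 0.25,
            "noncoding": 0.45,
            "other": 0.05,
        }
    )
    n_genes: int = 60
    n_direct_genes: int = 10
    plof_multiplier: tuple[float, ...] | None = None  # default linspace(0.3, 1)
    catalogue_coverage: float = 0.95
    pathogenic_fraction: float = 0.01
    ambiguous_fraction: float = 0.05
    missing_rate: float = 0.002
    high_missing_fraction: float = 0.01  # sites with elevated missingness
    high_missing_rate: float = 0.05
    mortality_intercept: float = 160.0
    mortality_slope: float = -400.0
    mortality_noise_sd: float = 25.0
    ancestry_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.fst = tuple(self.fst)[: self.n_populations]
        if len(self.fst) < self.n_populations:
            extra = np.linspace(0.02, 0.2, self.n_populations - len(self.fst))
            self.fst = self.fst + tuple(extra)
        for f in self.fst:
            if not (0.0 < f < 1.0):
                raise ValueError("drift F must be in (0, 1)")
        if self.admixture is None:
            A = np.eye(self.n_populations)
            if self.n_populations >= 3:
                A[-1] = 0.0
                A[-1, 0] = A[-1, 1] = 0.5
            self.admixture = A
        self.admixture = np.asarray(self.admixture, dtype=float)
        if self.admixture.shape[0] != self.n_populations:
            raise ValueError("admixture matrix needs one row per population")
        if np.any(self.admixture < 0) or np.any(
            np.abs(self.admixture.sum(axis=1) - 1) > 1e-9
        ):
            raise ValueError("admixture rows must be non-negative and sum to 1")
        if self.plof_multiplier is None:
            self.plof_multiplier = tuple(
                np.linspace(0.3, 1.0, self.n_populations)
            )
        if not (0.0 <= self.catalogue_coverage <= 1.0):
            raise ValueError("catalogue_coverage must be in [0, 1]")

    @property
    def population_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_populations)]


def simulate_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ancestral freq, per-population derived frequencies).

    Returns ``(p, pop_freq)`` with ``pop_freq`` shaped
    (n_populations, n_sites).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_comp = cfg.admixture.shape[1]
    p = rng.uniform(0.02, 0.98, size=cfg.n_sites)
    comp = np.empty((n_comp, cfg.n_sites))
    for k in range(n_comp):
        F = cfg.fst[k] if k < len(cfg.fst) else cfg.fst[-1]
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        comp[k] = rng.beta(a, b)
    pop_freq = cfg.admixture @ comp
    return p, pop_freq


def simulate_haplotypes(
    cfg: SimConfig,
    pop_freq: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Founder-mosaic haplotypes per population.

    Returns ``(haps, positions, genetic_pos)`` where ``haps`` is
    (2 * n_pops * samples_per_pop, n_sites) in derived (0/1) coding, ordered
    population-major, and positions are sorted 1-based bp.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    positions = np.sort(
        rng.choice(np.arange(1, cfg.chrom_length_bp), size=cfg.n_sites, replace=False)
    )
    genetic_pos = positions / 1e6 * cfg.cm_per_mb
    n_hap_pop = 2 * cfg.samples_per_pop
    blocks = []
    for pidx in range(cfg.n_populations):
        founders = (
            rng.random((cfg.n_founders, cfg.n_sites)) < pop_freq[pidx]
        ).astype(np.uint8)
        # mosaic copying path: founder index per haplotype per site
        switch = rng.random((n_hap_pop, cfg.n_sites)) < cfg.switch_rate
        switch[:, 0] = True
        draws = rng.integers(0, cfg.n_founders, size=(n_hap_pop, cfg.n_sites))
        seg = np.maximum.accumulate(
            np.where(switch, np.arange(cfg.n_sites)[None, :], -1), axis=1
        )
        path = np.take_along_axis(draws, seg, axis=1)
        blocks.append(founders[path, np.arange(cfg.n_sites)[None, :]])
    return np.concatenate(blocks, axis=0), positions, genetic_pos


def plant_sweep(
    haps: np.ndarray,
    genetic_pos: np.ndarray,
    positions: np.ndarray,
    pop_rows: slice,
    spec: SweepSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overwrite a fraction of one population's haplotypes by a sweep core.

    Returns a modified copy; the core site is the site nearest
    ``spec.core_pos`` and carriers are derived there.
    """
    haps = haps.copy()
    sub = haps[pop_rows]
    n = sub.shape[0]
    n_carriers = int(round(spec.carrier_fraction * n))
    if n_carriers < 2:
        raise ValueError("carrier_fraction * haplotypes < 2")
    core_pos = spec.core_pos
    core = int(np.argmin(np.abs(positions - core_pos)))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    donor = sub[rng.integers(0, n)].copy()
    donor[core] = 1
    d = np.abs(genetic_pos - genetic_pos[core])
    escape_p = 1.0 - np.exp(-d / spec.decay_scale_cM)
    escape = rng.random((n_carriers, sub.shape[1])) < escape_p
    sub[carriers] = np.where(escape, sub[carriers], donor[None, :])
    haps[pop_rows] = sub
    return haps


def _tile_genes(cfg: SimConfig, positions: np.ndarray) -> list[str]:
    width = cfg.chrom_length_bp / cfg.n_genes
    idx = np.minimum((positions // width).astype(int), cfg.n_genes - 1)
    return [f"gene{i + 1:04d}" for i in idx]


def simulate_cohort(cfg: SimConfig):
    """Full synthetic cohort.

    Returns ``(sites, geno, haps, manifest, truth)``; ``truth`` records the
    generating quantities the tests check against (population frequencies,
    sweep core site index, true burden ratios, direct/indirect gene sets).
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc, pop_freq = simulate_frequencies(cfg, rng)
    hap, positions, genetic_pos = simulate_haplotypes(cfg, pop_freq, rng)
    pops = cfg.population_ids
    n_hap_pop = 2 * cfg.samples_per_pop

    core_site = None
    if cfg.sweep is not None:
        target = cfg.sweep.core_pos or cfg.chrom_length_bp // 2
        # a sweep acts on a (pre-sweep) rare derived allele: pick the site
        # nearest the requested position that is rare in every population
        rare = hap.reshape(cfg.n_populations, n_hap_pop, -1).mean(axis=1).max(axis=0) < 0.25
        candidates = np.flatnonzero(rare)
        if candidates.size == 0:
            candidates = np.arange(cfg.n_sites)
        core_site = int(candidates[np.argmin(np.abs(positions[candidates] - target))])
        spec = SweepSpec(
            population=cfg.sweep.population,
            core_pos=int(positions[core_site]),
            carrier_fraction=cfg.sweep.carrier_fraction,
            decay_scale_cM=cfg.sweep.decay_scale_cM,
        )
        pidx = pops.index(spec.population)
        rows = slice(pidx * n_hap_pop, (pidx + 1) * n_hap_pop)
        hap = plant_sweep(hap, genetic_pos, positions, rows, spec, rng)

    # --- site annotations -------------------------------------------------
    n = cfg.n_sites
    genes = _tile_genes(cfg, positions)
    classes = list(cfg.effect_probs)
    probs = np.array([cfg.effect_probs[c] for c in classes], dtype=float)
    effect = rng.choice(classes, size=n, p=probs / probs.sum())
    known = rng.random(n) < cfg.catalogue_coverage
    catalogue = [frozenset({"simdb"}) if k else frozenset() for k in known]
    clinical = np.where(
        rng.random(n) < cfg.pathogenic_fraction, "pathogenic", None
    )

    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]
    direct = set(rng.choice(gene_ids, size=cfg.n_direct_genes, replace=False))
    indirect = set(gene_ids) - direct

    # --- population-specific pLOF thinning in direct genes ----------------
    plof_direct = np.array(
        [e == "pLOF" and g in direct for e, g in zip(effect, genes)]
    )
    for pidx, m in enumerate(cfg.plof_multiplier):
        if m >= 1.0:
            continue
        rows = slice(pidx * n_hap_pop, (pidx + 1) * n_hap_pop)
        drop = plof_direct & (rng.random(n) >= m)
        hap[rows, :] = np.where(drop[None, :], 0, hap[rows, :])

    # --- alleles, polarity, genotype dosages ------------------------------
    anc_base_idx = rng.integers(0, 4, size=n)
    anc_base = _BASES[anc_base_idx]
    ambiguous = rng.random(n) < cfg.ambiguous_fraction
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    # non-self, non-complement partners keep a site unambiguous
    unamb = {"A": ("C", "G"), "C": ("A", "T"), "G": ("A", "T"), "T": ("C", "G")}
    pick = rng.integers(0, 2, size=n)
    other = np.array(
        [
            complement[b] if amb else unamb[b][k]
            for b, amb, k in zip(anc_base, ambiguous, pick)
        ]
    )
    anc_is_ref = rng.random(n) < 0.8
    ref = np.where(anc_is_ref, anc_base, other)
    alt = np.where(anc_is_ref, other, anc_base)
    ancestral = anc_base

    site_df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "ancestral": ancestral,
            "gene_id": genes,
            "effect_class": effect,
            "catalogue_flags": catalogue,
            "clinical_class": clinical,
            "region_labels": [frozenset()] * n,
        }
    )
    sites = SiteTable(site_df)

    samples = [f"{pop}_s{j + 1:03d}" for pop in pops for j in range(cfg.samples_per_pop)]
    derived_dose = (
        hap.reshape(len(samples), 2, n).sum(axis=1).T.astype(np.int8)
    )  # sites x samples
    flip = ~anc_is_ref  # ancestral == alt: ALT dosage = 2 - derived dosage
    calls = np.where(flip[:, None], 2 - derived_dose, derived_dose).astype(np.int8)

    # missingness (genotypes only; phased haplotypes stay complete)
    site_rate = np.full(n, cfg.missing_rate)
    high = rng.random(n) < cfg.high_missing_fraction
    site_rate[high] = cfg.high_missing_rate
    miss = rng.random(calls.shape) < site_rate[:, None]
    calls = np.where(miss, -1, calls)

    sex = np.array(["male", "female"] * (len(samples) // 2 + 1))[: len(samples)]
    geno = GenotypeMatrix(sites, samples, calls, sex=sex)
    haps = HaplotypeMatrix(hap, samples, genetic_pos, positions)

    # --- manifest: geography, ancestry, mortality -------------------------
    lats = np.linspace(12.0, -25.0, cfg.n_populations)
    lons = np.linspace(0.0, 30.0, cfg.n_populations)
    n_comp = cfg.admixture.shape[1]
    anc_cols = [f"anc_c{k}" for k in range(n_comp)]
    sample_rows = []
    for pidx, pop in enumerate(pops):
        alpha = cfg.admixture[pidx] * cfg.ancestry_concentration + 1e-3
        props = rng.dirichlet(alpha, size=cfg.samples_per_pop)
        props = props / props.sum(axis=1, keepdims=True)
        for j in range(cfg.samples_per_pop):
            sample_rows.append(
                [samples[pidx * cfg.samples_per_pop + j], pop]
                + list(props[j])
            )
    sdf = pd.DataFrame(sample_rows, columns=["sample", "population"] + anc_cols)
    sdf = sdf.set_index("sample")
    sdf["sex"] = sex
    sdf["affected"] = [frozenset()] * len(sdf)

    # true burden ratio per population: segregating distinct pLOF sites
    plof = effect == "pLOF"
    in_direct = np.array([g in direct for g in genes])
    ratios = {}
    for pidx, pop in enumerate(pops):
        rows = slice(pidx * n_hap_pop, (pidx + 1) * n_hap_pop)
        seg = hap[rows].any(axis=0)
        d_count = int(np.sum(seg & plof & in_direct))
        i_count = int(np.sum(seg & plof & ~in_direct))
        ratios[pop] = d_count / i_count if i_count else np.nan
    ratio_vec = np.array([ratios[p] for p in pops])
    mortality = (
        cfg.mortality_intercept
        + cfg.mortality_slope * ratio_vec
        + rng.normal(0, cfg.mortality_noise_sd, size=cfg.n_populations)
    )
    pdf = pd.DataFrame(
        {
            "lat": lats,
            "lon": lons,
            "mortality_sim": np.maximum(mortality, 0.0),
        },
        index=pd.Index(pops, name="population"),
    )
    manifest = PopulationManifest(samples=sdf, populations=pdf)

    truth = {
        "ancestral_freq": p_anc,
        "pop_freq": pop_freq,
        "core_site": core_site,
        "sweep": cfg.sweep,
        "burden_ratio": ratios,
        "direct_genes": direct,
        "indirect_genes": indirect,
    }
    return sites, geno, haps, manifest, truth
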