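"""Site- and sample-level quality control.

The site filter cascade applies, in order: call rate, exact Hardy-Weinberg
test, minor allele frequency, and strand-ambiguous (A/T, C/G) removal; each
stage is counted on the survivors of the previous one.  Sample-level QC
prunes sites in linkage disequilibrium, estimates pairwise relatedness by
the method of moments (PiHAT), and greedily selects an unrelated subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, SiteTable


@dataclass
class QCReport:
    n_input: int
    removed: dict = field(default_factory=dict)  # filter -> count
    retained_sites: np.ndarray | None = None
    retained_samples: list[str] | None = None

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P is the summed probability of all heterozygote counts whose conditional
    probability (given the allele counts) does not exceed that of the
    observed count.  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_a = 2 * n_aa + n_Aa  # rare-allele count (relabel below if needed)
    n_A = 2 * n_AA + n_Aa
    if n_a > n_A:
        n_a, n_A = n_A, n_a
    if n_a == 0:
        return 1.0
    # unnormalized log-probabilities over all het counts with n_a's parity
    hets = np.arange(n_a % 2, n_a + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        hom_r = (n_a - h) // 2
        hom_c = n - h - hom_r
        return (
            h * np.log(2.0)
            - gammaln(hom_r + 1)
            - gammaln(h + 1)
            - gammaln(hom_c + 1)
        )

    lp = logprob(hets)
    lp -= lp.max()
    prob = np.exp(lp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa]
    if obs.size == 0:  # observed het count has impossible parity
        raise ValueError("heterozygote count inconsistent with allele count")
    p = prob[prob <= obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (calls == 0).sum(axis=1),
        (calls == 1).sum(axis=1),
        (calls == 2).sum(axis=1),
    )


def filter_sites(
    geno: GenotypeMatrix,
    sites: SiteTable,
    call_rate_min: float = 0.99,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.01,
    drop_ambiguous: bool = True,
) -> tuple[GenotypeMatrix, SiteTable, QCReport]:
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} outside [0, 1]")
    if not (0.0 <= hwe_p_min <= 1.0):
        raise ValueError("hwe_p_min outside [0, 1]")

    report = QCReport(n_input=len(sites))
    keep = np.ones(len(sites), dtype=bool)

    obs = geno.calls != MISSING
    call_rate = obs.sum(axis=1) / geno.n_samples
    fail = keep & (call_rate < call_rate_min)
    report.removed["call_rate"] = int(fail.sum())
    keep &= ~fail

    hwe_p = np.ones(len(sites))
    for i in np.flatnonzero(keep):
        row = geno.calls[i]
        row = row[row != MISSING]
        if row.size:
            hwe_p[i] = hwe_exact_test(
                int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
            )
    fail = keep & (hwe_p < hwe_p_min)
    report.removed["hwe"] = int(fail.sum())
    keep &= ~fail

    af = geno.alt_frequency()
    maf = np.minimum(af, 1 - af)
    fail = keep & (np.nan_to_num(maf, nan=0.0) < maf_min)
    report.removed["maf"] = int(fail.sum())
    keep &= ~fail

    if drop_ambiguous:
        fail = keep & sites.is_ambiguous
        report.removed["ambiguous"] = int(fail.sum())
        keep &= ~fail
    else:
        report.removed["ambiguous"] = 0

    report.retained_sites = np.flatnonzero(keep)
    return geno.subset_sites(keep), sites.subset(keep), report


def ld_prune(
    geno: GenotypeMatrix, r2_max: float = 0.15, window_bp: int = 1000
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns retained site indices.

    A site is dropped if its squared genotype correlation with any already
    retained site within ``window_bp`` exceeds ``r2_max``.
    """
    pos = geno.sites.df["pos"].to_numpy()
    chrom = geno.sites.df["chrom"].to_numpy()
    calls = np.where(geno.calls == MISSING, np.nan, geno.calls).astype(float)
    kept: list[int] = []
    for i in range(geno.n_sites):
        ok = True
        for j in reversed(kept):
            if chrom[j] != chrom[i] or pos[i] - pos[j] > window_bp:
                break
            x, y = calls[i], calls[j]
            m = ~(np.isnan(x) | np.isnan(y))
            if m.sum() < 3:
                continue
            xm, ym = x[m] - x[m].mean(), y[m] - y[m].mean()
            denom = np.sqrt((xm**2).sum() * (ym**2).sum())
            if denom == 0:
                continue
            r2 = ((xm * ym).sum() / denom) ** 2
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    return np.array(kept, dtype=int)


def estimate_relatedness(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise PiHAT by method-of-moments IBD estimation.

    Uses observed identity-by-state counts against their expectations under
    IBD states 0/1/2 given sample allele frequencies; estimates are clipped
    to [0, 1].  Expects LD-pruned input with >= 100 sites.
    """
    if geno.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = np.where(geno.calls == MISSING, np.nan, geno.calls).astype(float)
    p = np.nanmean(calls, axis=1) / 2.0
    q = 1 - p
    # per-site IBS-state expectations given IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e1_ibs1 = 2 * p * q
    e1_ibs2 = p**2 + q**2

    n_samp = geno.n_samples
    pihat = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            a, b = calls[:, i], calls[:, j]
            m = ~(np.isnan(a) | np.isnan(b))
            if m.sum() < 100:
                raise ValueError("need >= 100 shared non-missing sites per pair")
            diff = np.abs(a[m] - b[m])
            n_sites = m.sum()
            obs0 = (diff == 2).sum() / n_sites
            obs1 = (diff == 1).sum() / n_sites
            E0_0, E1_0 = e0_ibs0[m].mean(), e0_ibs1[m].mean()
            E1_1, E2_1 = e1_ibs1[m].mean(), e1_ibs2[m].mean()
            P0 = obs0 / E0_0 if E0_0 > 0 else 0.0
            P1 = (obs1 - P0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
            P0, P1 = np.clip(P0, 0, 1), np.clip(P1, 0, 1)
            P2 = np.clip(1 - P0 - P1, 0, 1)
            pihat[i, j] = pihat[j, i] = float(np.clip(P2 + 0.5 * P1, 0, 1))
    return pihat


def select_unrelated(
    pihat: np.ndarray,
    samples: list[str],
    pihat_max: float = 0.25,
    seed: int = 0,
) -> list[str]:
    """Greedy unrelated subset: repeatedly drop one (seeded-random) member of
    the most-related remaining pair until no pair exceeds ``pihat_max``."""
    rng = np.random.default_rng(seed)
    active = list(range(len(samples)))
    pihat = pihat.copy()
    while True:
        sub = pihat[np.ix_(active, active)]
        np.fill_diagonal(sub, 0)
        if sub.max() <= pihat_max:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        drop = active[i] if rng.random() < 0.5 else active[j]
        active.remove(drop)
    return [samples[i] for i in active]
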