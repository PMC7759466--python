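"""Allele-frequency differentiation: Hudson F_ST, the population branch
statistic, highly differentiated variant scanning, and the f3 admixture test.

Hudson's estimator is used as the ratio of averages,

    N_i = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_i = p1(1-p2) + p2(1-p1),          F_ST = sum(N) / sum(D),

with ``n`` the number of sampled alleles.  PBS converts pairwise F_ST to
branch lengths T = -ln(1 - F_ST) and isolates one population's branch.  The
f3 statistic E[(c-a)(c-b)] carries the finite-sample correction
c(1-c)/(n_C - 1) and a delete-one block jackknife over contiguous
physical blocks for its standard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PopulationManifest, SiteTable
from .frequencies import derived_counts


# ---------------------------------------------------------------------------
# Hudson F_ST and PBS

def hudson_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1, n2 = np.asarray(n1, float), np.asarray(n2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Ratio-of-averages Hudson F_ST over sites with positive denominator.

    Returns ``(fst, per_site_num, per_site_den)``.  Requires n >= 2 alleles
    in both populations at every used site.
    """
    num, den = hudson_components(p1, n1, p2, n2)
    use = np.isfinite(num) & np.isfinite(den) & (den > 0)
    if not use.any():
        raise ValueError("no informative sites for F_ST")
    return float(num[use].sum() / den[use].sum()), num, den


def pairwise_fst_matrix(
    geno: GenotypeMatrix, sites: SiteTable, manifest: PopulationManifest
) -> pd.DataFrame:
    pops = manifest.population_ids
    freq, count = {}, {}
    for pop in pops:
        d, n = derived_counts(geno, sites, manifest.members(pop))
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[pop] = d / n
        count[pop] = n
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            fst, _, _ = hudson_fst(freq[a], count[a], freq[b], count[b])
            out.loc[a, b] = out.loc[b, a] = max(fst, 0.0)
    return out


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> tuple[float, float, float]:
    """(PBS_A, PBS_B, PBS_C) from the three pairwise F_ST values."""
    for f in (fst_ab, fst_ac, fst_bc):
        if f >= 1.0:
            raise ValueError("F_ST must be < 1 for a finite branch length")
    t_ab = -np.log(1 - max(fst_ab, 0.0))
    t_ac = -np.log(1 - max(fst_ac, 0.0))
    t_bc = -np.log(1 - max(fst_bc, 0.0))
    return (
        (t_ab + t_ac - t_bc) / 2,
        (t_ab + t_bc - t_ac) / 2,
        (t_ac + t_bc - t_ab) / 2,
    )


def pbs_scan(
    geno: GenotypeMatrix,
    sites: SiteTable,
    manifest: PopulationManifest,
    focal: tuple[str, str, str],
    outgroup: str | None = None,
    maf_min: float = 0.01,
    p_outlier: float = 0.001,
) -> pd.DataFrame:
    """Per-site PBS for each focal population's branch, with outlier flags.

    For each pair (X, Y) of focal populations the branch of X is measured
    on the (X, Y, outgroup) triple; a site's PBS for X is the maximum over
    its pairings, following the one-population-at-a-time comparison.  With
    ``outgroup=None`` the third focal population serves as outgroup for
    each pair.  Outliers are sites above the empirical (1 - p) quantile of
    a branch's genome-wide distribution.  Sites with dataset MAF below
    ``maf_min`` or monomorphic everywhere are skipped.
    """
    pops = list(focal) + ([outgroup] if outgroup else [])
    freq, count = {}, {}
    for pop in pops:
        d, n = derived_counts(geno, sites, manifest.members(pop))
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[pop] = d / n
        count[pop] = n

    af = geno.alt_frequency()
    maf = np.minimum(af, 1 - af)
    usable = np.nan_to_num(maf, nan=0.0) >= maf_min
    poly = np.zeros(len(sites), dtype=bool)
    for pop in pops:
        f = freq[pop]
        poly |= np.nan_to_num(f, nan=0.0) * np.nan_to_num(1 - f, nan=0.0) > 0
    usable &= poly

    def branch(x: str, y: str, o: str) -> np.ndarray:
        n_xy, d_xy = hudson_components(freq[x], count[x], freq[y], count[y])
        n_xo, d_xo = hudson_components(freq[x], count[x], freq[o], count[o])
        n_yo, d_yo = hudson_components(freq[y], count[y], freq[o], count[o])
        out = np.full(len(sites), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_xy = np.clip(n_xy / d_xy, 0, 0.999999)
            f_xo = np.clip(n_xo / d_xo, 0, 0.999999)
            f_yo = np.clip(n_yo / d_yo, 0, 0.999999)
        t = lambda f: -np.log(1 - f)
        vals = (t(f_xy) + t(f_xo) - t(f_yo)) / 2
        out[usable] = vals[usable]
        return out

    a, b, c = focal
    result = pd.DataFrame({"chrom": sites.df["chrom"], "pos": sites.df["pos"]})
    pairs = {a: [(b, outgroup or c), (c, outgroup or b)],
             b: [(a, outgroup or c), (c, outgroup or a)],
             c: [(a, outgroup or b), (b, outgroup or a)]}
    for pop in focal:
        stacked = np.stack([branch(pop, y, o) for y, o in pairs[pop]])
        all_nan = np.all(np.isnan(stacked), axis=0)
        stacked[:, all_nan] = -np.inf
        scores = np.nanmax(stacked, axis=0)
        scores[all_nan] = np.nan
        result[f"pbs_{pop}"] = scores
        finite = np.isfinite(scores)
        if finite.any():
            thresh = np.quantile(scores[finite], 1 - p_outlier)
            result[f"outlier_{pop}"] = finite & (scores > thresh)
        else:
            result[f"outlier_{pop}"] = False
    return result


# ---------------------------------------------------------------------------
# Highly differentiated variants

def hdv_scan(
    pop_dafs: pd.DataFrame,
    sites: SiteTable,
    threshold: float = 0.40,
    masks: tuple[str, ...] = ("HBB_cluster", "HLA"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HDV records per population pair plus a 0.1-wide |dDAF| histogram.

    A record is kept when |DAF_i - DAF_j| strictly exceeds ``threshold``;
    sites in masked regions are reported with ``masked=True`` and excluded
    from headline counts.  The histogram covers all unmasked pairwise
    |dDAF| values in 0.1-wide bins (HDVs are its right tail).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be inside (0, 1)")
    pops = list(pop_dafs.columns)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    masked = np.zeros(len(sites), dtype=bool)
    for label in masks:
        masked |= sites.in_region(label)
    records = []
    all_deltas = []
    daf = pop_dafs.to_numpy()
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            b = pops[j]
            delta = np.abs(daf[:, i] - daf[:, j])
            all_deltas.append(delta[~masked & np.isfinite(delta)])
            hit = np.nan_to_num(delta, nan=0.0) > threshold
            for s in np.flatnonzero(hit):
                records.append(
                    (s, sites.df.loc[s, "chrom"], sites.df.loc[s, "pos"],
                     a, b, daf[s, i], daf[s, j], delta[s], bool(masked[s]))
                )
    hdvs = pd.DataFrame(
        records,
        columns=["site", "chrom", "pos", "pop1", "pop2", "daf1", "daf2",
                 "abs_delta", "masked"],
    )
    edges = np.arange(0.0, 1.0 + 1e-9, 0.1)
    hist = np.histogram(np.concatenate(all_deltas), bins=edges)[0]
    histogram = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "n_hdvs": hist}
    )
    return hdvs, histogram


def gwas_proximity_join(
    hdvs: pd.DataFrame,
    gwas_hits: pd.DataFrame,
    max_dist: int = 50_000,
    p_max: float = 5e-8,
) -> pd.DataFrame:
    """Annotate HDVs with qualifying GWAS hits within ``max_dist`` bp.

    ``gwas_hits`` needs columns chrom, pos, p (and optionally trait).  A
    hit qualifies when p < p_max and |pos difference| <= max_dist on the
    same chromosome.
    """
    hits = gwas_hits[gwas_hits["p"] < p_max]
    out = hdvs.copy()
    joined = []
    for r in out.itertuples(index=False):
        near = hits[
            (hits["chrom"] == r.chrom) & ((hits["pos"] - r.pos).abs() <= max_dist)
        ]
        joined.append(tuple(near["pos"]))
    out["gwas_hits"] = joined
    out["n_gwas_hits"] = [len(h) for h in joined]
    return out


# ---------------------------------------------------------------------------
# f3 admixture test

def f3_test(
    geno: GenotypeMatrix,
    sites: SiteTable,
    manifest: PopulationManifest,
    target: str,
    source_a: str,
    source_b: str,
    block_bp: float = 5e6,
) -> dict:
    """f3(target; A, B) with block-jackknife standard error and z-score.

    Per site: (c - a)(c - b) - c(1 - c)/(n_C - 1) using sample derived
    frequencies; a significantly negative f3 (large negative z) indicates
    the target is admixed between proxies of the two sources.
    """
    vals = {}
    counts = {}
    for pop in (target, source_a, source_b):
        d, n = derived_counts(geno, sites, manifest.members(pop))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[pop] = d / n
        counts[pop] = n
    if np.max(counts[target]) < 4:
        raise ValueError("target population needs at least 2 diploid samples")
    c, a, b = vals[target], vals[source_a], vals[source_b]
    n_c = counts[target].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = (c - a) * (c - b) - c * (1 - c) / (n_c - 1)
    use = np.isfinite(per_site)
    if use.sum() < 2:
        raise ValueError("not enough informative sites for f3")

    pos = sites.df["pos"].to_numpy()
    chrom = sites.df["chrom"].to_numpy()
    block_id = np.array(
        [f"{ch}:{int(p // block_bp)}" for ch, p in zip(chrom, pos)]
    )
    blocks = pd.unique(block_id[use])
    if len(blocks) < 2:
        raise ValueError("need at least 2 jackknife blocks")
    x = per_site[use]
    bid = block_id[use]
    f3 = float(x.mean())
    loo = np.array([x[bid != blk].mean() for blk in blocks])
    n_blocks = len(blocks)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    z = f3 / se if se > 0 else np.nan
    return {
        "target": target,
        "sources": (source_a, source_b),
        "f3": f3,
        "se": se,
        "z": float(z),
        "n_blocks": n_blocks,
        "n_sites": int(use.sum()),
    }
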