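"""Selective-sweep scans.

Two complementary statistics are implemented from first principles:

* **EHH / iHS** — extended haplotype homozygosity around a core site,
  integrated over genetic distance separately for carriers of the ancestral
  and derived allele; the unstandardized score ln(iHH_A / iHH_D) is
  standardized within 40 equal-width derived-allele-frequency bins so that
  scores are comparable across frequencies.

* **CLR** — a composite likelihood ratio contrasting a star-like sweep model
  against the genome-wide background site frequency spectrum.  Under the
  sweep model each of the n sampled lineages escapes the sweep independently
  with probability p_e(d) = 1 - exp(-alpha * d) at distance d from the swept
  site; non-escaped lineages carry the founder allele.  With background
  frequency q (drawn from the background SFS) the sampling probability of
  j derived copies is

      P(j | q, p_e) = sum_k Bin(k; n, p_e) [ q Bin(j-(n-k); k, q)
                                             + (1-q) Bin(j; k, q) ].

  alpha is maximized on a log-spaced grid with golden-section refinement;
  CLR = 2 (max log CL_sweep - log CL_background), floored at the neutral
  boundary so CLR >= 0.

Outlier calling is empirical: thresholds are quantiles of window scores
sampled across populations, mirroring a genome-wide null built from the
data itself rather than an asymptotic distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .datamodel import HaplotypeMatrix, WindowScoreTrack, window_of

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# EHH and iHS

def ehh_curve(
    haps: np.ndarray, core: int, allele: int, direction: int
) -> tuple[np.ndarray, np.ndarray]:
    """EHH at each marker from ``core`` outward in ``direction`` (+1/-1).

    Returns ``(site_indices, ehh_values)`` starting at the core itself
    (EHH = 1 by definition).  ``haps`` is the (n_hap, n_sites) 0/1 matrix.
    """
    carriers = np.flatnonzero(haps[:, core] == allele)
    n = len(carriers)
    if n < 2:
        raise ValueError("need at least 2 carriers of the core allele")
    denom = n * (n - 1) / 2
    stop = haps.shape[1] if direction > 0 else -1
    idx = list(range(core, stop, direction))
    labels = np.zeros(n, dtype=np.int64)
    ehh = np.empty(len(idx))
    ehh[0] = 1.0
    for step, s in enumerate(idx[1:], start=1):
        labels = labels * 2 + haps[carriers, s]
        _, labels = np.unique(labels, return_inverse=True)
        counts = np.bincount(labels)
        ehh[step] = (counts * (counts - 1) / 2).sum() / denom
    return np.array(idx), ehh


@njit(cache=True)
def _walk_ihh(
    haps: np.ndarray,
    carriers: np.ndarray,
    core: int,
    direction: int,
    genetic_pos: np.ndarray,
    cutoff: float,
) -> tuple[float, bool]:
    """Trapezoidal iHH on one flank; True when truncated by chromosome end.

    Maintains the partition of carrier haplotypes into distinct extended
    haplotypes as integer labels, compacted at every marker.
    """
    n = carriers.shape[0]
    denom = n * (n - 1) / 2.0
    labels = np.zeros(n, dtype=np.int64)
    newlab = np.empty(n, dtype=np.int64)
    keymap = np.empty(2 * n, dtype=np.int64)
    ihh = 0.0
    prev_ehh = 1.0
    prev_pos = genetic_pos[core]
    s = core
    while True:
        s += direction
        if s < 0 or s >= haps.shape[1]:
            return ihh, True  # ran off the chromosome before EHH < cutoff
        keymap[:] = -1
        nl = 0
        for i in range(n):
            key = 2 * labels[i] + haps[carriers[i], s]
            if keymap[key] == -1:
                keymap[key] = nl
                nl += 1
            newlab[i] = keymap[key]
        labels[:] = newlab
        pairs = 0.0
        counts = np.zeros(nl, dtype=np.int64)
        for i in range(n):
            counts[labels[i]] += 1
        for c in counts:
            pairs += c * (c - 1) / 2.0
        e = pairs / denom
        gap = abs(genetic_pos[s] - prev_pos)
        ihh += 0.5 * (prev_ehh + e) * gap
        prev_ehh = e
        prev_pos = genetic_pos[s]
        if e < cutoff:
            return ihh, False


def _ihh_one_side(
    haps: np.ndarray,
    core: int,
    allele: int,
    direction: int,
    genetic_pos: np.ndarray,
    cutoff: float,
) -> tuple[float, bool]:
    carriers = np.flatnonzero(haps[:, core] == allele)
    return _walk_ihh(
        haps, carriers, core, direction, np.asarray(genetic_pos, float), cutoff
    )


def ihs(
    haps: HaplotypeMatrix,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    n_bins: int = 40,
) -> pd.DataFrame:
    """Standardized iHS per qualifying site.

    Columns: site, pos, daf, ihh_a, ihh_d, ihs_unstd, ihs, bin, truncated.
    Sites whose DAF bin holds fewer than 2 scored sites get NaN.
    """
    H = haps.haps
    daf = H.mean(axis=0)
    maf = np.minimum(daf, 1 - daf)
    cores = np.flatnonzero(maf > maf_min)
    rows = []
    for core in cores:
        rec = {"site": core, "pos": haps.positions[core], "daf": daf[core]}
        trunc = False
        ok = True
        for allele, key in ((0, "ihh_a"), (1, "ihh_d")):
            if (H[:, core] == allele).sum() < 2:
                ok = False
                break
            left, tl = _ihh_one_side(H, core, allele, -1, haps.genetic_pos, ehh_cutoff)
            right, tr = _ihh_one_side(H, core, allele, +1, haps.genetic_pos, ehh_cutoff)
            rec[key] = left + right
            trunc |= tl or tr
        if not ok:
            continue
        rec["truncated"] = trunc
        if rec["ihh_a"] > 0 and rec["ihh_d"] > 0:
            rec["ihs_unstd"] = float(np.log(rec["ihh_a"] / rec["ihh_d"]))
        else:
            rec["ihs_unstd"] = np.nan
        rows.append(rec)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["bin"] = np.minimum((df["daf"] * n_bins).astype(int), n_bins - 1)
    df["ihs"] = np.nan
    for b, sub in df.groupby("bin"):
        scored = sub["ihs_unstd"].dropna()
        if len(scored) < 2 or scored.std(ddof=0) == 0:
            logger.warning("iHS bin %d has <2 scorable sites; scores left NaN", b)
            continue
        df.loc[sub.index, "ihs"] = (
            sub["ihs_unstd"] - scored.mean()
        ) / scored.std(ddof=0)
    return df


def ihs_window_fraction(
    ihs_df: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    population: str = "pop",
    window: int = 10_000,
    ihs_abs_min: float = 2.6,
    top_frac: float = 0.01,
) -> WindowScoreTrack:
    """Per-window fraction of SNVs with |iHS| above the outlier cutoff.

    Windows without any scored SNV are excluded from the ranking; the top
    ``top_frac`` of remaining windows are flagged, with boundary ties all
    flagged.
    """
    starts = np.arange(0, chrom_length, window)
    scored = ihs_df.dropna(subset=["ihs"])
    win = window_of(scored["pos"].to_numpy(), window)
    frac = np.full(len(starts), np.nan)
    n_snvs = np.zeros(len(starts), dtype=int)
    for w in np.unique(win):
        sel = win == w
        i = int(w // window)
        n_snvs[i] = sel.sum()
        frac[i] = float((scored.loc[sel, "ihs"].abs() > ihs_abs_min).mean())
    outlier = np.zeros(len(starts), dtype=bool)
    ranked = np.flatnonzero(n_snvs > 0)
    if ranked.size:
        k = max(1, int(np.floor(top_frac * ranked.size)))
        thresh = np.sort(frac[ranked])[::-1][k - 1]
        outlier[ranked] = frac[ranked] >= thresh
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + window, chrom_length),
            "score": frac,
            "n_snvs": n_snvs,
            "outlier": outlier,
        }
    )
    return WindowScoreTrack(population, df)


# ---------------------------------------------------------------------------
# CLR sweep scan

def background_sfs(j: np.ndarray, n: int, pseudocount: float = 0.5) -> np.ndarray:
    """Background SFS over derived counts 1..n-1, pseudo-count smoothed.

    The smoothing keeps every polymorphic class possible so no observed
    configuration has zero background likelihood.
    """
    j = np.asarray(j)
    j = j[(j >= 1) & (j <= n - 1)]
    counts = np.bincount(j, minlength=n)[1:n].astype(float)
    counts += pseudocount
    return counts / counts.sum()


def _sweep_likelihood_table(
    n: int, bg: np.ndarray, pe_grid: np.ndarray
) -> np.ndarray:
    """log P(j | p_e) marginalized over the background SFS.

    Returns array (len(pe_grid), n+1).  Precomputes the escape-count kernel
    B[k, j] = sum_i bg_i [q_i Bin(j - (n - k); k, q_i) + (1-q_i) Bin(j; k, q_i)]
    once, then the p_e dependence is a binomial mixture over k.
    """
    ks = np.arange(n + 1)
    js = np.arange(n + 1)
    qs = np.arange(1, n) / n  # background frequency classes
    # P[k, i, j] = Bin(j; k, q_i)
    P = stats.binom.pmf(js[None, None, :], ks[:, None, None], qs[None, :, None])
    # shifted: Bin(j - (n - k); k, q_i)
    Pshift = np.zeros_like(P)
    for k in ks:
        lo = n - k
        Pshift[k, :, lo:] = P[k, :, : n + 1 - lo]
    A = qs[None, :, None] * Pshift + (1 - qs)[None, :, None] * P
    B = np.einsum("i,kij->kj", bg, A)  # (n+1, n+1)
    W = stats.binom.pmf(ks[None, :], n, pe_grid[:, None])  # (n_pe, n+1)
    L = W @ B
    return np.log(np.maximum(L, 1e-300))


def clr_scan(
    derived: np.ndarray,
    positions: np.ndarray,
    n: int,
    chrom: str,
    chrom_length: int,
    population: str = "pop",
    bg: np.ndarray | None = None,
    window: int = 10_000,
    grid_spacing: int = 2_000,
    n_alpha: int = 64,
    n_refine: int = 3,
    alpha_range: tuple[float, float] = (1e-8, 1e-3),
    max_radius_bp: int = 100_000,
    background_mix: float = 0.05,
    exclude_mask: pd.DataFrame | None = None,
) -> tuple[WindowScoreTrack, pd.DataFrame]:
    """Composite-likelihood sweep scan on one chromosome of one population.

    ``derived`` are derived-allele counts (0..n) per site at ``positions``
    (1-based bp) among ``n`` haplotypes; the per-window score is the maximum
    CLR over grid points in the window.  ``exclude_mask`` (BED-like, already
    flank-extended) removes grid points and windows before scanning.

    ``background_mix`` blends a small background-SFS component into each
    site's sweep likelihood.  Near the swept site the pure model is
    degenerate (at escape probability 0 it only allows counts 0 or n), so a
    single site that deviates from it — an incomplete sweep's non-carriers,
    a mispolarized allele — would otherwise veto the whole region.

    Returns ``(track, grid_df)`` where ``grid_df`` holds per-grid-point CLR
    and the maximizing alpha (1/bp).
    """
    derived = np.asarray(derived)
    positions = np.asarray(positions)
    poly = (derived >= 1) & (derived <= n - 1)
    j_obs = derived[poly]
    pos = positions[poly]
    if bg is None:
        bg = background_sfs(j_obs, n)
    log_bg = np.log(np.maximum(bg, 1e-300))

    pe_grid = np.concatenate(
        [np.geomspace(1e-6, 0.999, 63), [1.0]]
    )
    log_tab = _sweep_likelihood_table(n, bg, pe_grid)
    if background_mix > 0:
        log_tab = np.log(
            (1 - background_mix) * np.exp(log_tab)
            + background_mix * np.concatenate([[1e-300], bg, [1e-300]])[None, :]
        )

    def site_loglik(pe: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Interpolate log P(j | p_e); pe and j broadcast to same shape."""
        pe = np.clip(pe, pe_grid[0], 1.0)
        hi = np.searchsorted(pe_grid, pe)
        hi = np.clip(hi, 1, len(pe_grid) - 1)
        lo = hi - 1
        w = (pe - pe_grid[lo]) / (pe_grid[hi] - pe_grid[lo])
        return (1 - w) * log_tab[lo, j] + w * log_tab[hi, j]

    alphas = np.geomspace(alpha_range[0], alpha_range[1], n_alpha)
    log_alphas = np.log(alphas)
    gr = (np.sqrt(5) - 1) / 2

    grid_x = np.arange(grid_spacing // 2, chrom_length, grid_spacing)
    if exclude_mask is not None and len(exclude_mask):
        bad = np.zeros(len(grid_x), dtype=bool)
        for r in exclude_mask.itertuples(index=False):
            if str(r.chrom) == str(chrom):
                bad |= (grid_x >= r.start) & (grid_x < r.end)
        grid_x = grid_x[~bad]

    clr = np.zeros(len(grid_x))
    alpha_hat = np.full(len(grid_x), np.nan)
    bg_ll = log_bg[j_obs - 1]
    for g, x in enumerate(grid_x):
        near = np.flatnonzero(np.abs(pos - x) <= max_radius_bp)
        if near.size == 0:
            continue
        d = np.abs(pos[near] - x).astype(float)
        j = j_obs[near]
        base = bg_ll[near].sum()

        def obj(log_a: np.ndarray) -> np.ndarray:
            pe = 1.0 - np.exp(-np.exp(log_a)[:, None] * d[None, :])
            return site_loglik(pe, j[None, :]).sum(axis=1) - base

        vals = obj(log_alphas)
        best = int(np.argmax(vals))
        lo = log_alphas[max(best - 1, 0)]
        hi = log_alphas[min(best + 1, n_alpha - 1)]
        a, b = lo, hi
        for _ in range(n_refine):
            m1 = b - gr * (b - a)
            m2 = a + gr * (b - a)
            v1, v2 = obj(np.array([m1, m2]))
            if v1 < v2:
                a = m1
            else:
                b = m2
        refined = float(obj(np.array([(a + b) / 2]))[0])
        score = max(vals[best], refined, 0.0)
        clr[g] = 2.0 * score
        alpha_hat[g] = np.exp((a + b) / 2)

    grid_df = pd.DataFrame(
        {"chrom": chrom, "grid_pos": grid_x, "clr": clr, "alpha": alpha_hat}
    )
    starts = np.arange(0, chrom_length, window)
    win = (grid_x // window).astype(int)
    score = np.full(len(starts), np.nan)
    n_pts = np.zeros(len(starts), dtype=int)
    for w in np.unique(win):
        sel = win == w
        score[w] = clr[sel].max()
        n_pts[w] = sel.sum()
    site_win = (pos // window).astype(int)
    n_snvs = np.bincount(site_win, minlength=len(starts))[: len(starts)]
    track_df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + window, chrom_length),
            "score": np.nan_to_num(score, nan=0.0),
            "n_snvs": n_snvs,
            "outlier": False,
        }
    )
    keep = n_pts > 0
    return WindowScoreTrack(population, track_df[keep].reset_index(drop=True)), grid_df


def empirical_threshold(
    tracks: list[WindowScoreTrack],
    n_sample: int = 10_000,
    p: float = 0.001,
    seed: int = 0,
) -> float:
    """Empirical (1 - p) score quantile from windows pooled across tracks.

    Windows are sampled without replacement; if fewer than ``n_sample`` are
    available all are used (with a warning).  Outliers are then scores
    strictly above the returned threshold.
    """
    scores = np.concatenate(
        [t.df.loc[t.df["n_snvs"] > 0, "score"].to_numpy() for t in tracks]
    )
    scores = scores[np.isfinite(scores)]
    rng = np.random.default_rng(seed)
    if len(scores) < n_sample:
        logger.warning(
            "only %d windows available (< %d); using all", len(scores), n_sample
        )
        sample = scores
    else:
        sample = rng.choice(scores, size=n_sample, replace=False)
    return float(np.quantile(sample, 1 - p))


def flag_outliers(track: WindowScoreTrack, threshold: float) -> WindowScoreTrack:
    df = track.df.copy()
    df["outlier"] = (df["score"] > threshold) & (df["n_snvs"] > 0)
    return WindowScoreTrack(track.population, df)


# ---------------------------------------------------------------------------
# eQTL enrichment and local-ancestry elevation

def _overlap_count(regions: pd.DataFrame, eqtl_pos: dict[str, np.ndarray]) -> int:
    total = 0
    for r in regions.itertuples(index=False):
        pos = eqtl_pos.get(str(r.chrom))
        if pos is None:
            continue
        total += int(np.sum((pos >= r.start) & (pos < r.end)))
    return total


def eqtl_enrichment(
    outlier_regions: pd.DataFrame,
    background_regions: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    n_resample: int = 1000,
    n_outer: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tissue t-score distribution for eQTL overlap of outlier regions.

    Observed = eQTL count within outlier regions; null = counts within
    ``n_resample`` random background subsets of the same size; t = (obs -
    null mean) / null SD.  The outer loop repeats the resampling to give a
    t distribution per tissue (columns: tissue, t_mean, t_sd, t_scores,
    observed).  Tissues with zero null SD are reported with NaN t.
    """
    if len(background_regions) < len(outlier_regions):
        raise ValueError("background region set smaller than outlier set")
    rng = np.random.default_rng(seed)
    k = len(outlier_regions)
    rows = []
    for tissue, sub in eqtl_table.groupby("tissue"):
        eqtl_pos = {
            str(c): np.sort(s["pos"].to_numpy()) for c, s in sub.groupby("chrom")
        }
        obs = _overlap_count(outlier_regions, eqtl_pos)
        # per-region background overlap counts, then subset sums
        bg_counts = np.array(
            [
                _overlap_count(background_regions.iloc[[i]], eqtl_pos)
                for i in range(len(background_regions))
            ]
        )
        t_scores = np.empty(n_outer)
        for o in range(n_outer):
            # equal-sized subsets drawn without replacement
            keys = rng.random((n_resample, len(bg_counts)))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            null = bg_counts[idx].sum(axis=1)
            sd = null.std(ddof=0)
            t_scores[o] = (obs - null.mean()) / sd if sd > 0 else np.nan
        rows.append(
            {
                "tissue": tissue,
                "observed": obs,
                "t_mean": float(np.nanmean(t_scores)) if np.any(np.isfinite(t_scores)) else np.nan,
                "t_sd": float(np.nanstd(t_scores)) if np.any(np.isfinite(t_scores)) else np.nan,
                "t_scores": t_scores,
            }
        )
    return pd.DataFrame(rows)


def ancestry_elevation(
    gene_ancestry: pd.Series, window_ancestry: np.ndarray, k_sd: float = 3.0
) -> pd.Series:
    """Flag genes whose mean local ancestry exceeds the genome-wide mean by
    more than ``k_sd`` standard deviations of the per-window distribution."""
    window_ancestry = np.asarray(window_ancestry, dtype=float)
    mu = np.nanmean(window_ancestry)
    sd = np.nanstd(window_ancestry)
    return gene_ancestry > mu + k_sd * sd
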