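"""Geography-genetics concordance and runs of homozygosity.

The Procrustes test embeds both the great-circle geographic distance matrix
and the genetic (F_ST) distance matrix by classical principal coordinate
analysis, finds the optimal translation/scaling/rotation superimposing the
two configurations, and summarizes fit as t0 = sqrt(1 - D) where D is the
minimized sum of squared differences (both configurations scaled to unit
trace).  Significance comes from permuting population labels of the genetic
matrix.

ROH detection reports *maximal* runs of homozygous genotypes per sample
subject to the constraint set (minimum SNV count, at most 1 heterozygous and
5 missing calls, minimum physical span and SNV density), classified by
length: class A < 500 kb, class B 500 kb-1.5 Mb, class C > 1.5 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .datamodel import MISSING, GenotypeMatrix, SiteTable

# WGS84
_A = 6378.137  # equatorial radius, km
_F = 1 / 298.257223563
_B = _A * (1 - _F)


def _vincenty_km(lat1, lon1, lat2, lon2, tol=1e-12, max_iter=200) -> float:
    """Vincenty inverse geodesic distance on the WGS84 ellipsoid (km).

    Falls back to the half meridian arc for non-convergent near-antipodal
    pairs (error there is well under the geographic uncertainty of a
    population centroid).
    """
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1, U2 = np.arctan((1 - _F) * np.tan(phi1)), np.arctan((1 - _F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sm = (
            cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = _F / 16 * cos2_alpha * (4 + _F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        # antipodal fallback: half the meridian circumference 2aE(e)
        e2 = 1 - (_B / _A) ** 2
        return float(2 * _A * ellipe(e2))
    u2 = cos2_alpha * (_A**2 - _B**2) / _B**2
    A_ = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B_ = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    d_sigma = B_ * sin_sigma * (
        cos_2sm
        + B_ / 4 * (
            cos_sigma * (-1 + 2 * cos_2sm**2)
            - B_ / 6 * cos_2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sm**2)
        )
    )
    return float(_B * A_ * (sigma - d_sigma))


def great_circle_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ellipsoidal distances (km) from a lat/lon table (degrees)."""
    if (coords["lat"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (coords["lon"].abs() > 360).any():
        raise ValueError("longitude outside [-360, 360]")
    ids = list(coords.index)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _vincenty_km(
                coords.iloc[i]["lat"], coords.iloc[i]["lon"],
                coords.iloc[j]["lat"], coords.iloc[j]["lon"],
            )
    return pd.DataFrame(D, index=ids, columns=ids)


def pcoa(dist: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Classical principal coordinate embedding of a distance matrix."""
    D2 = np.asarray(dist, float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:n_dims]
    w_pos = np.maximum(w[order], 0.0)
    return v[:, order] * np.sqrt(w_pos)


def _procrustes_t0(X: np.ndarray, Y: np.ndarray) -> float:
    """Similarity sqrt(1 - D) after centering, unit-trace scaling and the
    optimal rotation of Y onto X."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.sqrt((Xc**2).sum())
    ny = np.sqrt((Yc**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("degenerate configuration")
    Xc, Yc = Xc / nx, Yc / ny
    s = np.linalg.svd(Yc.T @ Xc, compute_uv=False)
    D = 1 - s.sum() ** 2
    return float(np.sqrt(max(1 - D, 0.0)))


@dataclass
class ProcrustesResult:
    t0: float
    p_value: float
    n_perm: int
    n_dims: int


def procrustes_test(
    coords: pd.DataFrame,
    fst_matrix: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    n_dims: int = 2,
) -> ProcrustesResult:
    """Procrustes concordance of geography and genetic distance.

    The null permutes the population labels of the F_ST matrix, which is
    equivalent to permuting rows of its principal-coordinate embedding;
    P = (1 + #{t_perm >= t_obs}) / (1 + n_perm).
    """
    pops = list(coords.index)
    if len(pops) < 4:
        raise ValueError("need at least 4 populations")
    F = fst_matrix.loc[pops, pops].to_numpy(float)
    if not np.allclose(F, F.T):
        raise ValueError("F_ST matrix must be symmetric")
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse P value")
    geo = pcoa(great_circle_matrix(coords).to_numpy(), n_dims)
    gen = pcoa(F, n_dims)
    t_obs = _procrustes_t0(geo, gen)
    rng = np.random.default_rng(seed)
    n = len(pops)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _procrustes_t0(geo, gen[perm]) >= t_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ProcrustesResult(t0=t_obs, p_value=float(p), n_perm=n_perm, n_dims=n_dims)


# ---------------------------------------------------------------------------
# Runs of homozygosity

ROH_CLASS_BOUNDS = (500_000, 1_500_000)  # A < 500 kb <= B <= 1.5 Mb < C


def _classify(length: int) -> str:
    if length < ROH_CLASS_BOUNDS[0]:
        return "A"
    if length <= ROH_CLASS_BOUNDS[1]:
        return "B"
    return "C"


def detect_roh(
    geno: GenotypeMatrix,
    sites: SiteTable,
    min_snvs: int = 100,
    min_density: float = 1 / 50_000,
    max_het: int = 1,
    max_miss: int = 5,
    min_window_bp: int = 100_000,
) -> pd.DataFrame:
    """Maximal homozygous runs per sample, classified A/B/C by length.

    A segment qualifies when it holds >= ``min_snvs`` SNVs spanning
    >= ``min_window_bp`` bp at >= ``min_density`` SNVs/bp, with at most
    ``max_het`` heterozygous and ``max_miss`` missing calls; reported
    segments cannot be extended in either direction without breaking the
    het/missing constraints.  Overlapping maximal candidates (a tolerated
    het sitting at either edge) are resolved greedily left to right so the
    calls per sample are non-overlapping.
    """
    pos_all = sites.df["pos"].to_numpy()
    chrom_all = sites.df["chrom"].to_numpy()
    rows = []
    for chrom in pd.unique(chrom_all):
        cmask = chrom_all == chrom
        pos = pos_all[cmask]
        if np.any(np.diff(pos) <= 0):
            raise ValueError("sites must be sorted by position")
        calls_c = geno.calls[cmask]
        for sidx, sample in enumerate(geno.samples):
            g = calls_c[:, sidx]
            het = (g == 1).astype(int)
            mis = (g == MISSING).astype(int)
            chet = np.concatenate([[0], np.cumsum(het)])
            cmis = np.concatenate([[0], np.cumsum(mis)])
            n = len(g)
            left = 0
            prev_left = -1
            for right in range(n):
                while (
                    chet[right + 1] - chet[left] > max_het
                    or cmis[right + 1] - cmis[left] > max_miss
                ):
                    left += 1
                # maximal when the next extension right would force left up,
                # i.e. emit at each right where left will increase (or end)
                if right == n - 1:
                    emit = True
                else:
                    nxt_het = chet[right + 2] - chet[left]
                    nxt_mis = cmis[right + 2] - cmis[left]
                    emit = nxt_het > max_het or nxt_mis > max_miss
                if emit and left > prev_left:
                    n_snv = right - left + 1
                    start, end = int(pos[left]), int(pos[right])
                    length = end - start + 1
                    if (
                        n_snv >= min_snvs
                        and length >= min_window_bp
                        and n_snv / length >= min_density
                        and not (
                            rows
                            and rows[-1]["sample"] == sample
                            and rows[-1]["chrom"] == chrom
                            and start - 1 < rows[-1]["end"]
                        )
                    ):
                        rows.append(
                            {
                                "sample": sample,
                                "chrom": chrom,
                                "start": start - 1,  # BED convention
                                "end": end,
                                "n_snvs": n_snv,
                                "n_het": int(chet[right + 1] - chet[left]),
                                "n_missing": int(cmis[right + 1] - cmis[left]),
                                "length": length,
                                "roh_class": _classify(length),
                            }
                        )
                    prev_left = left
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "n_snvs", "n_het",
                 "n_missing", "length", "roh_class"],
    )


def fhat_inbreeding(geno: GenotypeMatrix) -> pd.Series:
    """Method-of-moments inbreeding coefficient per sample.

    F = (observed hom - expected hom) / (n - expected hom) with expectations
    from sample allele frequencies.
    """
    calls = np.where(geno.calls == MISSING, np.nan, geno.calls).astype(float)
    p = np.nanmean(calls, axis=1) / 2.0
    exp_het = 2 * p * (1 - p)
    out = {}
    for j, s in enumerate(geno.samples):
        g = calls[:, j]
        m = ~np.isnan(g) & np.isfinite(exp_het)
        n = m.sum()
        o_hom = (g[m] != 1).sum()
        e_hom = (1 - exp_het[m]).sum()
        out[s] = float((o_hom - e_hom) / (n - e_hom)) if n > e_hom else np.nan
    return pd.Series(out, name="fhat")


def roh_summary(segments: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-sample total ROH length (bp) and count per class."""
    idx = pd.Index(samples, name="sample")
    out = pd.DataFrame(0, index=idx, columns=["A_bp", "B_bp", "C_bp", "A_n", "B_n", "C_n"])
    for r in segments.itertuples(index=False):
        out.loc[r.sample, f"{r.roh_class}_bp"] += r.length
        out.loc[r.sample, f"{r.roh_class}_n"] += 1
    return out
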