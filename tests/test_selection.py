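"""EHH/iHS against a brute-force pairwise oracle, CLR model behaviour,
empirical thresholds, eQTL enrichment and ancestry elevation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from afroscan import selection
from afroscan.datamodel import HaplotypeMatrix


# ---------------------------------------------------------------------------
# Brute-force oracle: EHH from pairwise haplotype identity, same integration

def ehh_pairwise_oracle(haps, core, allele, x):
    """EHH at marker x for core-allele carriers, by pair enumeration."""
    carriers = np.flatnonzero(haps[:, core] == allele)
    n = len(carriers)
    lo, hi = min(core, x), max(core, x)
    ident = 0
    for a in range(n):
        for b in range(a + 1, n):
            if np.array_equal(
                haps[carriers[a], lo : hi + 1], haps[carriers[b], lo : hi + 1]
            ):
                ident += 1
    return ident / (n * (n - 1) / 2)


def ihs_oracle(haps, gpos, core, cutoff=0.05):
    """Unstandardized iHS via the pairwise EHH oracle with the same
    trapezoidal truncated integration."""
    out = {}
    for allele, key in ((0, "a"), (1, "d")):
        total = 0.0
        for direction in (-1, +1):
            prev_e, prev_g, ihh = 1.0, gpos[core], 0.0
            s = core
            while True:
                s += direction
                if s < 0 or s >= haps.shape[1]:
                    break
                e = ehh_pairwise_oracle(haps, core, allele, s)
                ihh += 0.5 * (prev_e + e) * abs(gpos[s] - prev_g)
                prev_e, prev_g = e, gpos[s]
                if e < cutoff:
                    break
            total += ihh
        out[key] = total
    return np.log(out["a"] / out["d"]) if out["a"] > 0 and out["d"] > 0 else np.nan


def _random_haps(seed, n_hap=16, n_sites=50):
    rng = np.random.default_rng(seed)
    haps = (rng.random((n_hap, n_sites)) < rng.uniform(0.2, 0.8, n_sites)).astype(
        np.uint8
    )
    pos = np.sort(rng.choice(np.arange(1, 500_000), n_sites, replace=False))
    return haps, pos, pos / 1e6


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        haps = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.uint8), (6, 1))
        idx, ehh = selection.ehh_curve(haps, 2, 1, +1)
        np.testing.assert_allclose(ehh, 1.0)

    def test_two_by_two_split_gives_one_third(self):
        # 4 carriers splitting into groups {2, 2}: EHH = 2/C(4,2) = 1/3
        haps = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1]], dtype=np.uint8
        )
        _, ehh = selection.ehh_curve(haps, 0, 1, +1)
        assert ehh[1] == pytest.approx(1 / 3)

    def test_fully_distinct_haplotypes_reach_zero(self):
        haps = np.array(
            [[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.uint8
        )
        _, ehh = selection.ehh_curve(haps, 0, 1, +1)
        assert ehh[2] == 0.0

    def test_monotone_non_increasing(self):
        for seed in range(5):
            haps, _, _ = _random_haps(seed, n_hap=20, n_sites=40)
            _, ehh = selection.ehh_curve(haps, 0, int(haps[0, 0]), +1)
            assert np.all(np.diff(ehh) <= 1e-12)

    def test_matches_pairwise_oracle(self):
        haps, _, _ = _random_haps(3, n_hap=16, n_sites=30)
        core = 10
        idx, ehh = selection.ehh_curve(haps, core, 1, +1)
        for k, x in enumerate(idx):
            assert ehh[k] == pytest.approx(
                ehh_pairwise_oracle(haps, core, 1, int(x)), abs=1e-12
            )

    def test_single_carrier_rejected(self):
        haps = np.zeros((4, 3), dtype=np.uint8)
        haps[0, 1] = 1
        with pytest.raises(ValueError):
            selection.ehh_curve(haps, 1, 1, +1)


class TestIhs:
    def test_equals_brute_force_oracle(self):
        """Unstandardized iHS matches the O(n^2 m) pairwise oracle exactly
        on 16-haplotype x 50-site fixtures."""
        for seed in range(3):
            haps, pos, gpos = _random_haps(seed, n_hap=16, n_sites=50)
            hm = HaplotypeMatrix(haps, [f"s{j}" for j in range(8)], gpos, pos)
            df = selection.ihs(hm, maf_min=0.05).set_index("site")
            checked = 0
            for core in df.index:
                expect = ihs_oracle(haps, gpos, int(core))
                got = df.loc[core, "ihs_unstd"]
                if np.isnan(expect):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-10)
                    checked += 1
            assert checked >= 10

    def test_equal_ihh_gives_zero_unstandardized(self):
        # symmetric fixture: ancestral and derived carriers mirror each other
        block = np.array(
            [[0, 0, 0, 0, 0], [0, 1, 0, 1, 0], [1, 0, 1, 0, 1], [1, 1, 1, 1, 1]],
            dtype=np.uint8,
        )
        haps = np.vstack([block, 1 - block])
        pos = np.arange(1, 6) * 1000
        hm = HaplotypeMatrix(haps, [f"s{j}" for j in range(4)], pos / 1e6, pos)
        df = selection.ihs(hm, maf_min=0.05)
        mid = df[df["site"] == 2]
        assert mid["ihs_unstd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardized_scores_have_unit_moments_per_bin(self, small_cohort):
        haps = small_cohort["haps"]
        man = small_cohort["manifest"]
        rows = haps.haplotypes_of(man.members("P2"))
        hm = HaplotypeMatrix(rows, man.members("P2"), haps.genetic_pos,
                             haps.positions)
        df = selection.ihs(hm)
        for b, sub in df.dropna(subset=["ihs"]).groupby("bin"):
            if len(sub) >= 2:
                assert abs(sub["ihs"].mean()) < 1e-10
                assert abs(sub["ihs"].std(ddof=0) - 1) < 1e-10


class TestIhsWindowFraction:
    def _df(self, scores, positions):
        return pd.DataFrame(
            {"site": np.arange(len(scores)), "pos": positions, "ihs": scores}
        )

    def test_all_outliers_score_one(self):
        df = self._df([3.0, -3.0, 2.7], [1000, 2000, 3000])
        track = selection.ihs_window_fraction(df, "1", 10_000)
        assert track.df.loc[0, "score"] == 1.0

    def test_normal_scores_match_tail_mass(self):
        """Standard-normal scores give mean window fraction ~ 2(1-Phi(2.6))."""
        rng = np.random.default_rng(0)
        n = 200_000
        df = self._df(rng.standard_normal(n), np.arange(1, n + 1) * 50)
        track = selection.ihs_window_fraction(df, "1", n * 50)
        expected = 2 * (1 - norm.cdf(2.6))
        assert track.df["score"].mean() == pytest.approx(expected, rel=0.1)

    def test_boundary_ties_all_flagged(self):
        # 10 windows, all with identical score: ties at the 1% boundary
        pos = np.arange(10) * 10_000 + 500
        df = self._df([3.0] * 10, pos + 1)
        track = selection.ihs_window_fraction(df, "1", 100_000)
        assert track.df["outlier"].all()

    def test_empty_windows_excluded_from_ranking(self):
        df = self._df([3.0], [95_000])
        track = selection.ihs_window_fraction(df, "1", 100_000)
        assert track.df["n_snvs"].iloc[:-1].sum() == 0
        assert not track.df["outlier"].iloc[:-1].any()
        assert track.df["outlier"].iloc[-1]


class TestClr:
    def _neutral_counts(self, seed, n=40, n_sites=400, L=1_000_000):
        rng = np.random.default_rng(seed)
        q = rng.uniform(0.02, 0.98, n_sites)
        j = rng.binomial(n, q)
        pos = np.sort(rng.choice(np.arange(1, L), n_sites, replace=False))
        return j, pos, n, L

    def test_scores_are_non_negative(self):
        j, pos, n, L = self._neutral_counts(0)
        track, grid = selection.clr_scan(j, pos, n, "1", L, grid_spacing=20_000,
                                         n_alpha=12)
        assert (grid["clr"] >= 0).all()

    def test_escape_saturated_model_reduces_to_background(self):
        """With alpha forced so large that p_e ~ 1 everywhere, the sweep
        model collapses onto the background SFS and CLR ~ 0."""
        j, pos, n, L = self._neutral_counts(1)
        track, grid = selection.clr_scan(
            j, pos, n, "1", L, grid_spacing=50_000, n_alpha=2,
            alpha_range=(0.5, 1.0), n_refine=0,
        )
        assert grid["clr"].max() < 0.5

    def test_background_sfs_smoothing_covers_all_classes(self):
        j = np.array([1, 1, 2, 5])
        bg = selection.background_sfs(j, n=10)
        assert bg.sum() == pytest.approx(1.0)
        assert (bg > 0).all()

    def test_planted_sweep_peaks_at_core(self, small_cohort):
        haps = small_cohort["haps"]
        man = small_cohort["manifest"]
        truth = small_cohort["truth"]
        rows = haps.haplotypes_of(man.members("P1"))
        track, grid = selection.clr_scan(
            rows.sum(axis=0), haps.positions, rows.shape[0], "1",
            small_cohort["cfg"].chrom_length_bp, grid_spacing=5000, n_alpha=16,
        )
        peak = grid.loc[grid["clr"].idxmax(), "grid_pos"]
        core_pos = haps.positions[truth["core_site"]]
        assert abs(peak - core_pos) < 50_000


class TestEmpiricalThreshold:
    def _track(self, scores):
        n = len(scores)
        df = pd.DataFrame(
            {
                "chrom": "1",
                "start": np.arange(n) * 10_000,
                "end": np.arange(1, n + 1) * 10_000,
                "score": scores,
                "n_snvs": 5,
                "outlier": False,
            }
        )
        from afroscan.datamodel import WindowScoreTrack

        return WindowScoreTrack("P", df)

    def test_uniform_scores_quantile_oracle(self):
        rng = np.random.default_rng(0)
        track = self._track(rng.uniform(0, 1, 20_000))
        thr = selection.empirical_threshold([track], n_sample=10_000, p=0.001,
                                            seed=1)
        assert thr == pytest.approx(0.999, abs=0.002)

    def test_constant_scores_give_zero_outliers(self):
        track = self._track(np.full(500, 7.0))
        thr = selection.empirical_threshold([track], n_sample=100, seed=0)
        flagged = selection.flag_outliers(track, thr)
        assert thr == 7.0
        assert not flagged.df["outlier"].any()  # strict >

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        track = self._track(rng.uniform(0, 1, 15_000))
        a = selection.empirical_threshold([track], seed=42)
        b = selection.empirical_threshold([track], seed=42)
        assert a == b


class TestEqtlEnrichment:
    def _regions(self, starts, chrom="1", width=10_000):
        return pd.DataFrame(
            {"chrom": chrom, "start": list(starts),
             "end": [s + width for s in starts]}
        )

    def test_null_t_scores_center_on_zero(self):
        rng = np.random.default_rng(0)
        bg = self._regions(np.arange(0, 4_000_000, 10_000))
        out = self._regions(rng.choice(np.arange(0, 4_000_000, 10_000), 30,
                                       replace=False))
        eqtls = pd.DataFrame(
            {"chrom": "1",
             "pos": rng.integers(0, 4_000_000, 300),
             "tissue": "liver"}
        )
        res = selection.eqtl_enrichment(out, bg, eqtls, n_resample=200,
                                        n_outer=20, seed=1)
        assert abs(res.loc[0, "t_mean"]) < 1.0

    def test_planted_eqtls_give_large_t(self):
        out = self._regions(np.arange(0, 300_000, 10_000))
        bg = self._regions(np.arange(300_000, 4_000_000, 10_000))
        both = pd.concat([out, bg], ignore_index=True)
        eqtls = pd.DataFrame(
            {"chrom": "1", "pos": out["start"] + 5_000, "tissue": "liver"}
        )
        res = selection.eqtl_enrichment(out, both, eqtls, n_resample=200,
                                        n_outer=10, seed=2)
        assert res.loc[0, "t_mean"] > 3

    def test_no_eqtls_reports_missing_t(self):
        out = self._regions([0])
        bg = self._regions(np.arange(10_000, 200_000, 10_000))
        eqtls = pd.DataFrame({"chrom": ["2"], "pos": [5], "tissue": ["liver"]})
        res = selection.eqtl_enrichment(out, bg, eqtls, n_resample=50,
                                        n_outer=5, seed=3)
        assert np.isnan(res.loc[0, "t_mean"])

    def test_small_background_rejected(self):
        with pytest.raises(ValueError):
            selection.eqtl_enrichment(
                self._regions([0, 10_000]), self._regions([0]),
                pd.DataFrame({"chrom": [], "pos": [], "tissue": []}),
            )


class TestAncestryElevation:
    def test_uniform_ancestry_flags_nothing(self):
        genes = pd.Series([0.3, 0.3], index=["g1", "g2"])
        flags = selection.ancestry_elevation(genes, np.full(100, 0.3))
        assert not flags.any()

    def test_three_and_a_half_sd_is_flagged(self):
        rng = np.random.default_rng(0)
        wins = rng.normal(0.3, 0.02, 5000)
        mu, sd = wins.mean(), wins.std()
        genes = pd.Series(
            [mu + 3.5 * sd, mu + 2.5 * sd], index=["hi", "mid"]
        )
        flags = selection.ancestry_elevation(genes, wins)
        assert flags["hi"] and not flags["mid"]

    def test_hand_computed_threshold(self):
        wins = np.array([0.1, 0.2, 0.3, 0.4])  # mean 0.25, sd ~0.1118
        genes = pd.Series({"a": 0.60, "b": 0.58})
        flags = selection.ancestry_elevation(genes, wins, k_sd=3.0)
        thr = 0.25 + 3 * np.std(wins)
        assert flags["a"] == (0.60 > thr)
        assert flags["b"] == (0.58 > thr)
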