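"""Hudson F_ST, PBS, HDV scanning, GWAS joins and the f3 admixture test."""

import numpy as np
import pandas as pd
import pytest

from afroscan import differentiation as diff
from afroscan.datamodel import GenotypeMatrix
from afroscan.simulate import SimConfig, simulate_cohort

from conftest import make_manifest, make_sites


class TestHudsonFst:
    def test_fixed_difference_gives_unity(self):
        fst, num, den = diff.hudson_fst(
            np.array([1.0]), np.array([20]), np.array([0.0]), np.array([20])
        )
        assert fst == pytest.approx(1.0)
        assert num[0] / den[0] == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # p1=0.2, p2=0.8, 11 alleles each: N=0.328, D=0.68, ratio 0.48235...
        fst, num, den = diff.hudson_fst(
            np.array([0.2]), np.array([11]), np.array([0.8]), np.array([11])
        )
        assert num[0] == pytest.approx(0.328)
        assert den[0] == pytest.approx(0.68)
        assert fst == pytest.approx(0.328 / 0.68, rel=1e-12)
        assert fst == pytest.approx(0.48235, abs=1e-5)

    def test_identical_frequencies_vanish_within_bias_bound(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 2000)
        n = np.full_like(p, 200)
        fst, _, _ = diff.hudson_fst(p, n, p, n)
        assert abs(fst) <= 2 / (200 - 1)

    def test_population_swap_symmetry(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)
        n = np.full(100, 30)
        a, _, _ = diff.hudson_fst(p1, n, p2, n)
        b, _, _ = diff.hudson_fst(p2, n, p1, n)
        assert a == pytest.approx(b, rel=1e-12)

    def test_no_informative_sites_rejected(self):
        with pytest.raises(ValueError):
            diff.hudson_fst(np.array([0.0]), np.array([10]),
                            np.array([0.0]), np.array([10]))


class TestPbs:
    def test_all_zero(self):
        assert diff.pbs(0, 0, 0) == (0, 0, 0)

    def test_closed_form_example(self):
        a, b, c = diff.pbs(0.1, 0.1, 0.0)
        assert a == pytest.approx(-np.log(0.9), rel=1e-12)
        assert a == pytest.approx(0.10536, abs=1e-5)

    def test_symmetry_when_two_branches_match(self):
        a, b, c = diff.pbs(0.1, 0.2, 0.1)  # F_AB = F_BC
        assert a == pytest.approx(c, rel=1e-12)

    def test_additivity_over_branches(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            f = rng.uniform(0, 0.5, 3)
            t = -np.log(1 - f)
            a, b, c = diff.pbs(*f)
            assert a + b + c == pytest.approx(t.sum() / 2, rel=1e-10)

    def test_fst_of_one_rejected(self):
        with pytest.raises(ValueError):
            diff.pbs(1.0, 0.1, 0.1)


class TestPbsScan:
    def _cohort(self, seed=0, boost_sites=(), boost_pop=0):
        cfg = SimConfig(
            seed=seed, n_populations=4, samples_per_pop=20, n_sites=2000,
            chrom_length_bp=2_000_000, fst=(0.05, 0.05, 0.05, 0.1),
            admixture=np.eye(4), sweep=None, missing_rate=0.0,
            high_missing_fraction=0.0,
        )
        sites, geno, haps, man, _ = simulate_cohort(cfg)
        if boost_sites:
            # plant extreme divergence: fix derived in one population only
            calls = geno.calls.copy()
            idx = geno.sample_index(man.members(man.population_ids[boost_pop]))
            flip = sites.ancestral_is_alt
            for s in boost_sites:
                calls[s, idx] = 0 if flip[s] else 2
            geno = GenotypeMatrix(sites, geno.samples, calls)
        return sites, geno, man

    def test_planted_divergence_flags_only_that_branch(self):
        # pick sites at intermediate frequency elsewhere, then fix the
        # derived allele in P1 only: extreme divergence on branch P1
        sites0, geno0, man = self._cohort(seed=5)
        from afroscan.frequencies import population_daf

        dafs = population_daf(geno0, sites0, man)
        mid = (
            (dafs[["P2", "P3", "P4"]] > 0.35) & (dafs[["P2", "P3", "P4"]] < 0.65)
        ).all(axis=1)
        planted = list(np.flatnonzero(mid.to_numpy())[:3])
        sites, geno, man = self._cohort(seed=5, boost_sites=planted)
        res = diff.pbs_scan(geno, sites, man, ("P1", "P2", "P3"), outgroup="P4",
                            p_outlier=0.005)
        assert res.loc[planted, "outlier_P1"].all()
        assert not res.loc[planted, "outlier_P2"].any()
        assert not res.loc[planted, "outlier_P3"].any()

    def test_null_outlier_fraction_matches_nominal(self):
        sites, geno, man = self._cohort(seed=6)
        res = diff.pbs_scan(geno, sites, man, ("P1", "P2", "P3"), outgroup="P4",
                            p_outlier=0.01)
        finite = res["pbs_P1"].notna()
        frac = res.loc[finite, "outlier_P1"].mean()
        n = finite.sum()
        # binomial CI around nominal p (quantile ties make it slightly lower)
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)
        assert frac >= 0.01 - 3 * np.sqrt(0.01 * 0.99 / n)

    def test_maf_filter_removes_rare_sites(self):
        sites, geno, man = self._cohort(seed=7)
        af = geno.alt_frequency()
        rare = np.nan_to_num(np.minimum(af, 1 - af)) < 0.01
        res = diff.pbs_scan(geno, sites, man, ("P1", "P2", "P3"), outgroup="P4")
        assert res.loc[rare, "pbs_P1"].isna().all()


class TestHdvScan:
    def _sites(self, n, region_labels=None):
        return make_sites(
            n=n,
            region_labels=region_labels or [frozenset()] * n,
        )

    def test_threshold_is_strict(self):
        sites = self._sites(2)
        dafs = pd.DataFrame({"A": [0.85, 0.80], "B": [0.40, 0.40]})
        hdvs, _ = diff.hdv_scan(dafs, sites)  # deltas 0.45 and 0.40
        assert set(hdvs["site"]) == {0}

    def test_mask_excluded_from_headline_counts(self):
        labels = [frozenset()] * 20
        labels[3] = frozenset({"HBB_cluster"})
        sites = self._sites(20, region_labels=labels)
        daf_a = np.full(20, 0.1)
        daf_b = np.full(20, 0.1)
        for s in (1, 3, 7, 11):
            daf_b[s] = 0.9
        dafs = pd.DataFrame({"A": daf_a, "B": daf_b})
        hdvs, hist = diff.hdv_scan(dafs, sites)
        assert len(hdvs) == 4
        assert hdvs["masked"].sum() == 1
        assert len(hdvs[~hdvs["masked"]]) == 3
        assert hist["n_hdvs"].sum() == 20 - 1  # unmasked deltas only

    def test_histogram_uses_tenth_bins(self):
        sites = self._sites(3)
        dafs = pd.DataFrame({"A": [0.95, 0.55, 0.20], "B": [0.10, 0.10, 0.10]})
        _, hist = diff.hdv_scan(dafs, sites)
        assert len(hist) == 10
        assert hist.loc[8, "n_hdvs"] == 1  # delta 0.85 in [0.8, 0.9)
        assert hist.loc[4, "n_hdvs"] == 1  # delta 0.45
        assert hist.loc[1, "n_hdvs"] == 1  # delta 0.10 in [0.1, 0.2)

    def test_pair_order_invariance(self):
        sites = self._sites(5)
        rng = np.random.default_rng(3)
        dafs = pd.DataFrame({"A": rng.uniform(0, 1, 5), "B": rng.uniform(0, 1, 5)})
        h1, _ = diff.hdv_scan(dafs, sites)
        h2, _ = diff.hdv_scan(dafs[["B", "A"]], sites)
        assert set(h1["site"]) == set(h2["site"])

    def test_bad_threshold_rejected(self):
        sites = self._sites(1)
        dafs = pd.DataFrame({"A": [0.9], "B": [0.1]})
        with pytest.raises(ValueError):
            diff.hdv_scan(dafs, sites, threshold=1.2)


class TestGwasJoin:
    def _hdvs(self):
        return pd.DataFrame(
            {"site": [0, 1, 2], "chrom": "1", "pos": [100_000, 400_000, 900_000]}
        )

    def test_hand_computed_join(self):
        hits = pd.DataFrame(
            {
                "chrom": ["1"] * 5,
                "pos": [60_000, 149_000, 390_000, 460_000, 5_000_000],
                "p": [1e-9, 1e-9, 1e-9, 1e-9, 1e-9],
            }
        )
        out = diff.gwas_proximity_join(self._hdvs(), hits)
        # 60 kb and 149 kb flank the first HDV within range; 390 kb is 10 kb
        # from the second; 460 kb misses it by 60 kb > 50 kb
        assert out["n_gwas_hits"].tolist() == [2, 1, 0]

    def test_distance_boundary_inclusive(self):
        hits = pd.DataFrame({"chrom": ["1"], "pos": [150_000], "p": [1e-9]})
        out = diff.gwas_proximity_join(self._hdvs(), hits)
        assert out.loc[0, "n_gwas_hits"] == 1  # exactly 50 kb away

    def test_subthreshold_p_excluded(self):
        hits = pd.DataFrame({"chrom": ["1"], "pos": [100_000], "p": [1e-7]})
        out = diff.gwas_proximity_join(self._hdvs(), hits)
        assert out["n_gwas_hits"].sum() == 0


class TestF3:
    def _admixed_cohort(self, seed, mix=0.5, n_sites=3000):
        A = np.array([[1, 0, 0], [0, 1, 0], [mix, 1 - mix, 0]])
        cfg = SimConfig(
            seed=seed, n_populations=3, samples_per_pop=25, n_sites=n_sites,
            chrom_length_bp=3_000_000, fst=(0.1, 0.1, 0.1), admixture=A,
            sweep=None, missing_rate=0.0, high_missing_fraction=0.0,
        )
        sites, geno, _, man, _ = simulate_cohort(cfg)
        return sites, geno, man

    def test_admixed_target_is_negative(self):
        sites, geno, man = self._admixed_cohort(seed=1)
        res = diff.f3_test(geno, sites, man, "P3", "P1", "P2", block_bp=3e5)
        assert res["f3"] < 0
        assert res["z"] < -3

    def test_unadmixed_drifted_target_is_positive(self):
        A = np.eye(3)
        cfg = SimConfig(
            seed=2, n_populations=3, samples_per_pop=25, n_sites=3000,
            chrom_length_bp=3_000_000, fst=(0.1, 0.1, 0.15), admixture=A,
            sweep=None, missing_rate=0.0, high_missing_fraction=0.0,
        )
        sites, geno, _, man, _ = simulate_cohort(cfg)
        res = diff.f3_test(geno, sites, man, "P3", "P1", "P2", block_bp=3e5)
        assert res["f3"] > 0

    def test_degenerate_identical_populations_near_zero(self):
        rng = np.random.default_rng(4)
        n_samp = 60
        p = rng.uniform(0.1, 0.9, 500)
        calls = rng.binomial(2, p[:, None], size=(500, 3 * n_samp)).astype(np.int8)
        sites = make_sites(n=500, spacing=10_000)
        samples = [f"{pop}_s{j}" for pop in "ABC" for j in range(n_samp)]
        geno = GenotypeMatrix(sites, samples, calls)
        man = make_manifest(list("ABC"), n_samp)
        res = diff.f3_test(geno, sites, man, "C", "A", "B", block_bp=5e5)
        assert abs(res["f3"]) < 5e-3

    def test_jackknife_se_tracks_replicate_sd(self):
        """Block-jackknife SE agrees with the SD of f3 across independent
        replicates within 20%."""
        f3s, ses = [], []
        for seed in range(100):
            sites, geno, man = self._admixed_cohort(seed + 10, n_sites=1200)
            res = diff.f3_test(geno, sites, man, "P3", "P1", "P2", block_bp=3e5)
            f3s.append(res["f3"])
            ses.append(res["se"])
        ratio = np.mean(ses) / np.std(f3s)
        assert 0.8 < ratio < 1.25

    def test_tiny_target_rejected(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, 0.5, size=(200, 11)).astype(np.int8)
        sites = make_sites(n=200, spacing=1000)
        samples = [f"A_s{j}" for j in range(5)] + [
            f"B_s{j}" for j in range(5)
        ] + ["C_s0"]
        geno = GenotypeMatrix(sites, samples, calls)
        man = make_manifest(["A", "B"], 5)
        man.samples.loc["C_s0"] = man.samples.iloc[0]
        man.samples.loc["C_s0", "population"] = "C"
        man.populations.loc["C"] = man.populations.iloc[0]
        with pytest.raises(ValueError, match="target"):
            diff.f3_test(geno, sites, man, "C", "A", "B")
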