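"""Medically relevant variation: loss-of-function burden vs mortality,
pathogenic-allele summaries, actionable-gene panels, and allele-frequency
vignettes for clinically important African loci.

The burden statistic per population is the number of distinct putative
loss-of-function (pLOF) sites segregating in genes *directly* implicated in
a disease, normalized by the count in *indirectly* implicated genes (to
absorb mutation-rate and annotation differences between populations).  Its
association with per-population mortality is judged against a null of
random gene sets matched in gene count to the direct list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, GenotypeMatrix, PopulationManifest, SiteTable
from .frequencies import derived_counts


def plof_gene_counts(
    sites: SiteTable, geno: GenotypeMatrix, manifest: PopulationManifest
) -> pd.DataFrame:
    """Genes x populations matrix of segregating distinct pLOF site counts."""
    plof = (sites.df["effect_class"] == "pLOF").to_numpy()
    genes = sites.df["gene_id"].to_numpy()
    out = {}
    for pop in manifest.population_ids:
        d, _ = derived_counts(geno, sites, manifest.members(pop))
        seg = np.nan_to_num(d, nan=0.0) > 0
        mask = plof & seg
        out[pop] = pd.Series(genes[mask]).value_counts()
    df = pd.DataFrame(out).fillna(0).astype(int)
    df.index.name = "gene_id"
    return df


def lof_burden_ratio(
    gene_counts: pd.DataFrame,
    direct: set[str],
    indirect: set[str],
    strict: bool = False,
) -> pd.Series:
    """Per-population direct/indirect segregating pLOF ratio."""
    d = gene_counts.reindex(sorted(direct)).fillna(0).sum(axis=0)
    i = gene_counts.reindex(sorted(indirect)).fillna(0).sum(axis=0)
    if (i == 0).any():
        if strict:
            raise ValueError("indirect pLOF count is zero for some population")
        return (d / i.replace(0, np.nan)).rename("burden_ratio")
    return (d / i).rename("burden_ratio")


def burden_mortality_test(
    gene_counts: pd.DataFrame,
    direct: set[str],
    indirect: set[str],
    mortality: pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Observed burden-mortality R^2 against a random-gene-set null.

    Each iteration redraws |direct| genes from the annotated genes outside
    the direct list, recomputes the per-population ratio (normalizing by the
    true indirect set) and its squared Pearson correlation with mortality.
    Reports the observed R^2, the null mean and s.e.m., the signed-rank
    Wilcoxon P of (null - observed) — the one-vs-distribution convention —
    and a rank-based empirical P (fraction of null R^2 >= observed), which
    is uniform under the null.
    """
    pops = [p for p in gene_counts.columns if p in mortality.index]
    if len(pops) < 3:
        raise ValueError("need at least 3 populations with mortality rates")
    mort = mortality.loc[pops].to_numpy(float)
    if np.std(mort) == 0:
        raise ValueError("zero variance in mortality")

    obs_ratio = lof_burden_ratio(gene_counts, direct, indirect).loc[pops]
    if obs_ratio.std() == 0 or obs_ratio.isna().any():
        raise ValueError("burden ratios degenerate (zero variance or undefined)")
    obs_r2 = float(stats.pearsonr(obs_ratio.to_numpy(), mort)[0] ** 2)

    rng = np.random.default_rng(seed)
    all_genes = [g for g in gene_counts.index if g not in direct]
    counts = gene_counts.loc[:, pops]
    indirect_tot = (
        counts.reindex(sorted(indirect)).fillna(0).sum(axis=0).to_numpy(float)
    )
    pool = counts.loc[all_genes].to_numpy(float)
    null_r2 = np.empty(n_iter)
    k = len(direct)
    for it in range(n_iter):
        pick = rng.choice(len(all_genes), size=k, replace=False)
        num = pool[pick].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = num / indirect_tot
        if np.std(ratio) == 0 or not np.all(np.isfinite(ratio)):
            null_r2[it] = np.nan
            continue
        null_r2[it] = stats.pearsonr(ratio, mort)[0] ** 2
    valid = null_r2[np.isfinite(null_r2)]
    diffs = valid - obs_r2
    if np.all(diffs == 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(diffs[diffs != 0]).pvalue)
    empirical_p = float((np.sum(valid >= obs_r2) + 1) / (len(valid) + 1))
    return {
        "observed_r2": obs_r2,
        "ratios": obs_ratio,
        "null_r2": null_r2,
        "null_mean": float(np.nanmean(null_r2)),
        "null_sem": float(np.nanstd(null_r2) / np.sqrt(len(valid))),
        "wilcoxon_p": wilcoxon_p,
        "empirical_p": empirical_p,
        "n_iter": n_iter,
    }


# ---------------------------------------------------------------------------
# Clinical burden summaries

def clinvar_burden(
    sites: SiteTable,
    geno: GenotypeMatrix,
    manifest: PopulationManifest,
    classes: tuple[str, ...] = ("pathogenic",),
) -> dict:
    """Pathogenic-allele carriage: per-individual dosage sums, cohort
    median/range, and per-population variant frequencies with a common
    (MAF > 0.05) flag."""
    sel = sites.df["clinical_class"].isin(classes).to_numpy()
    calls = geno.calls[sel]
    # pathogenic allele = ALT for these records (clinical assertion is on ALT)
    dose = np.where(calls == MISSING, 0, calls)
    per_individual = pd.Series(dose.sum(axis=0), index=geno.samples, name="alleles")
    per_pop_rows = []
    freq_rows = []
    site_idx = np.flatnonzero(sel)
    for pop in manifest.population_ids:
        members = manifest.members(pop)
        idx = geno.sample_index(members)
        vals = per_individual.loc[members]
        per_pop_rows.append(
            (pop, float(vals.median()), int(vals.min()), int(vals.max()))
        )
        sub = geno.calls[np.ix_(site_idx, idx)]
        obs = sub != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(obs, sub, 0).sum(axis=1) / np.maximum(
                2 * obs.sum(axis=1), 1
            )
        for s, f in zip(site_idx, af):
            freq_rows.append(
                (pop, sites.df.loc[s, "chrom"], sites.df.loc[s, "pos"], float(f),
                 bool(min(f, 1 - f) > 0.05))
            )
    return {
        "per_individual": per_individual,
        "per_population": pd.DataFrame(
            per_pop_rows, columns=["population", "median", "min", "max"]
        ),
        "frequencies": pd.DataFrame(
            freq_rows, columns=["population", "chrom", "pos", "maf_alt", "common"]
        ),
    }


def acmg_panel_burden(
    sites: SiteTable,
    geno: GenotypeMatrix,
    panel_genes: list[str],
    classes: tuple[str, ...] = ("pathogenic", "likely_pathogenic"),
) -> pd.DataFrame:
    """Carrier and allele counts per panel gene for reportable variants."""
    if not panel_genes:
        raise ValueError("empty gene panel")
    sel = (
        sites.df["gene_id"].isin(panel_genes)
        & sites.df["clinical_class"].isin(classes)
    ).to_numpy()
    rows = []
    for gene in panel_genes:
        mask = sel & (sites.df["gene_id"] == gene).to_numpy()
        calls = geno.calls[mask]
        dose = np.where(calls == MISSING, 0, calls)
        carriers = int(((dose > 0).any(axis=0)).sum()) if mask.any() else 0
        alleles = int(dose.sum()) if mask.any() else 0
        rows.append((gene, carriers, alleles))
    return pd.DataFrame(rows, columns=["gene", "carriers", "alleles"])


# ---------------------------------------------------------------------------
# Clinical vignettes

def _site_at(sites: SiteTable, chrom: str, pos: int) -> int | None:
    hit = np.flatnonzero(
        (sites.df["chrom"] == chrom).to_numpy() & (sites.df["pos"] == pos).to_numpy()
    )
    return int(hit[0]) if hit.size else None


def _alt_freq_subset(geno: GenotypeMatrix, site: int, idx: np.ndarray) -> float:
    calls = geno.calls[site, idx]
    obs = calls != MISSING
    if obs.sum() == 0:
        return np.nan
    return float(np.where(obs, calls, 0).sum() / (2 * obs.sum()))


def vignette_frequencies(
    sites: SiteTable,
    geno: GenotypeMatrix,
    manifest: PopulationManifest,
    config: dict,
) -> pd.DataFrame:
    """Per-population frequencies for the clinical vignettes.

    ``config`` maps vignette names to site specs (``{"chrom":…, "pos":…}``):

    * ``hbs`` — sickle allele frequency, excluding samples carrying the
      ``HbSS`` affected flag.
    * ``apol1_g1`` / ``apol1_g2`` — kidney-disease risk loci; the risk
      genotype is a total of >= 2 risk alleles across the two (mutually
      exclusive) haplotypes: G1/G1, G1/G2 or G2/G2.
    * ``g6pd_202`` / ``g6pd_376`` — X-linked deficiency alleles; male
      hemizygotes contribute a single allele.
    * ``hla_b5701`` — abacavir-hypersensitivity proxy allele frequency.

    Absent vignette sites are reported as NaN, never zero.
    """
    def locate(key):
        spec = config.get(key)
        if spec is None:
            return None
        return _site_at(sites, str(spec["chrom"]), int(spec["pos"]))

    loc = {k: locate(k) for k in
           ("hbs", "apol1_g1", "apol1_g2", "g6pd_202", "g6pd_376", "hla_b5701")}
    rows = []
    for pop in manifest.population_ids:
        members = manifest.members(pop)
        idx = geno.sample_index(members)
        rec = {"population": pop}

        if loc["hbs"] is not None:
            unaffected = [
                s for s in members
                if "HbSS" not in manifest.samples.loc[s, "affected"]
            ]
            u_idx = geno.sample_index(unaffected)
            rec["hbs_freq"] = (
                _alt_freq_subset(geno, loc["hbs"], u_idx) if len(u_idx) else np.nan
            )
        else:
            rec["hbs_freq"] = np.nan

        if loc["apol1_g1"] is not None and loc["apol1_g2"] is not None:
            g1 = geno.calls[loc["apol1_g1"], idx]
            g2 = geno.calls[loc["apol1_g2"], idx]
            called = (g1 != MISSING) & (g2 != MISSING)
            risk = (np.where(called, g1, 0) + np.where(called, g2, 0)) >= 2
            rec["apol1_risk_genotype_freq"] = (
                float(risk[called].mean()) if called.any() else np.nan
            )
        else:
            rec["apol1_risk_genotype_freq"] = np.nan

        for key, col in (("g6pd_202", "g6pd_202a_freq"), ("g6pd_376", "g6pd_376g_freq")):
            s = loc[key]
            if s is None:
                rec[col] = np.nan
                continue
            alleles = 0
            total = 0
            for m in members:
                j = geno.sample_index([m])[0]
                call = geno.calls[s, j]
                if call == MISSING:
                    continue
                if geno.sex[j] == "male":  # hemizygous: one X allele
                    alleles += int(call > 0)
                    total += 1
                else:
                    alleles += int(call)
                    total += 2
            rec[col] = alleles / total if total else np.nan

        s = loc["hla_b5701"]
        rec["hla_b5701_freq"] = _alt_freq_subset(geno, s, idx) if s is not None else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("population")
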