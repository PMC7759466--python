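# Methods

## Data model and polarization

All statistics operate on derived/ancestral polarized frequencies: the
derived allele frequency (DAF) at a site is the frequency of the
non-ancestral allele among non-missing calls, where the ancestral state
comes from the VCF `AA` tag (a sidecar annotation column overrides it).
Sites with unknown ancestral state are kept in the tables but excluded from
every DAF-based analysis; a population with no non-missing calls at a site
yields a missing frequency, never zero. VCF positions are 1-based; all
window and interval outputs are 0-based half-open (BED). Multiallelic and
non-SNV records are skipped at read time with a logged count — resolving
them properly requires read-level evidence that a genotype matrix cannot
carry. Missing genotypes are excluded from both numerator and denominator
of every frequency.

## Synthetic cohorts

The generator produces cohorts with the statistical structure the scans
assume, not a demographic reconstruction.

**Allele frequencies** follow the Balding–Nichols model: an ancestral
frequency p ~ Uniform(0.02, 0.98) per site; each ancestry component with
drift parameter F draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F);
admixed populations mix component frequencies linearly through the
admixture matrix. Defaults: six populations spanning F = 0.02–0.20 (the
range typical of continental-scale human divergence), the last population a
50/50 mix of the first two components.

**Haplotypes** are mosaics of 100 founder haplotypes per population
(founders drawn i.i.d. Bernoulli at the population frequency; each sample
haplotype copies a founder and switches to a random founder with
probability 0.05 per site). This produces linkage disequilibrium with a
decay length of roughly 20 sites while keeping realized allele frequencies
within sampling error of their targets; 100 founders keep the extra
within-population variance (pq/100) small relative to between-population
drift, which matters for f3 and relatedness behaviour. The genetic map is a
constant 1 cM/Mb.

**Site density** defaults to 12,000 sites on a 4-Mb chromosome (3 SNVs/kb),
the order of within-population segregating density in high-coverage WGS.
Density is what lets 10-kb-window statistics localize: at much sparser
density a window holds so few SNVs that window fractions and window maxima
become unstable.

**The planted sweep** is star-like: the core site is the site nearest the
requested position whose pre-sweep derived frequency is below 0.25 in every
population (a sweep acts on a recent, initially rare allele); a fraction
(default 0.85) of the target population's haplotypes is overwritten by one
donor haplotype carrying the derived core allele, with per-site escape
probability 1 − exp(−d/λ) at map distance d (default λ = 0.1 cM) restoring
the original allele. Escapes are independent per carrier and site.

**Annotations and metadata**: genes tile the chromosome (default 60, of
which 10 form the "direct" disease set); effect classes are multinomial
with P(pLOF) = 0.02; a catalogue flag marks each site "known" with
probability 0.95, so ~5% of sites are novel; coordinates lie on an arc of
the African continent. Per-population pLOF thinning (multipliers 0.3–1.0
across populations) removes derived alleles at direct-gene pLOF sites,
creating a true burden gradient; mortality per population is
160 − 400 × (true burden ratio) + N(0, 25) deaths per 100,000, truncated
at 0 — the noise level puts the population-level R² between burden and
mortality near 0.5. A genotype missingness of 0.2% (1% of sites elevated
to 5%) gives the call-rate filter realistic casualties.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic demographic history and
recombination-map heterogeneity; genotyping error and batch structure;
background selection; linked phenotypes. The mortality model is
deliberately a clean linear signal plus noise: it tests the statistical
machinery, not epidemiology.

## Quality control

Site filters apply in a fixed order — call rate ≥ 0.99, exact
Hardy–Weinberg P ≥ 1e-6, MAF ≥ 0.01, strand-ambiguous (A/T, C/G)
removal — with each stage counted on the survivors of the previous one;
re-running the cascade on its own output removes nothing. The HWE test is
the exact conditional test: given the allele counts, P is the summed
probability of all heterozygote counts no more probable than the observed
one (heterozygote phase contributes the 2^h multiplicity), computed in log
space with a relative tie tolerance of 1e-12.

LD pruning is a greedy left-to-right scan (drop a site whose squared
genotype correlation with any retained site within 1,000 bp exceeds 0.15).
Relatedness is the method-of-moments IBD estimate: observed
identity-by-state fractions against their expectations under IBD 0/1/2
given sample allele frequencies, solved sequentially and clipped to [0, 1];
PiHAT = P(IBD=2) + P(IBD=1)/2. Negative moment estimates occur and are
clipped, matching standard tool behaviour. The unrelated subset is chosen
greedily: repeatedly drop one seeded-random member of the most related
remaining pair until no pair exceeds PiHAT 0.25.

## Discovery

A variant is novel when absent from every supplied catalogue, except sites
fixed derived in all populations whose derived allele is the reference
allele — these are treated as ancestral-state artefacts and excluded.
Per-individual novel counts use carrier status (≥ 1 derived allele), not
dosage, in a seeded subsample per population (default 24, the smallest
cohort size). Cumulative discovery curves are running unions over a
population ordering; the common-only variant removes population-singletons
first. The relative SFS per effect class is built on 48 sampled alleles,
with missing-data sites down-projected by rescaling the derived count to
48 and rounding; rare means DAF ≤ 0.01 (inclusive).

## Differentiation

Hudson's F_ST estimator is used as a ratio of averages,
N = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) and
D = p1(1−p2) + p2(1−p1), summed over sites with D > 0. It is the standard
unbiased two-population estimator; the original analysis toolchain is not
reproduced here, so the estimator is a documented substitution. PBS
converts pairwise F_ST to branch lengths T = −ln(1−F_ST); per-site PBS
clips negative F_ST components at 0 and caps them below 1. The per-site
scan computes each focal population's branch against each pairing with the
outgroup and takes the maximum, flagging sites above the empirical
(1 − 0.001) quantile of that branch's genome-wide distribution.

HDVs use a strict threshold (|ΔDAF| > 0.40); masked regions (the HBB
cluster and HLA, supplied as region labels or BED) are reported but
excluded from headline counts. The histogram covers all unmasked pairwise
|ΔDAF| values in 0.1 bins, so HDVs are its right tail. GWAS joins annotate
each HDV with genome-wide-significant (P < 5e-8) hits within 50 kb
(inclusive).

The f3 statistic is the site mean of (c−a)(c−b) − c(1−c)/(n_C−1) with
sample derived frequencies and the target's allele count n_C; the standard
error is a delete-one block jackknife over contiguous fixed-width physical
blocks (default 5 Mb, scaled down in tests to keep ≥ 8 blocks per
chromosome), and z = f3/SE. A significantly negative f3 indicates
admixture of the target between proxies of the two sources.

## Selection scans

**EHH/iHS.** EHH at distance x from a core is the probability that two
random carriers of the core allele are identical over [core, x],
Σ_h C(n_h, 2)/C(n, 2); it is computed by maintaining the partition of
carriers into distinct extended haplotypes (numba-compiled inner loop,
verified exactly against an O(n²m) pairwise-identity oracle). iHH is the
trapezoidal integral of EHH against map distance on each flank, truncated
when EHH < 0.05 or at the chromosome end (truncated cores are flagged but
kept, the cited tool's default behaviour). Unstandardized
iHS = ln(iHH_A/iHH_D) for sites with MAF > 0.05, standardized within 40
equal-width DAF bins (bins with fewer than two scorable sites yield
missing scores). Window scores are the fraction of scored SNVs with
|iHS| > 2.6 per 10-kb window; the top 1% of windows with ≥ 1 scored SNV
are outliers, with boundary ties all flagged.

**CLR.** The composite likelihood ratio contrasts a star-like sweep model
with the genome-wide background SFS (pseudo-count-smoothed with 0.5 per
class so every polymorphic class has support). Each of n lineages escapes
the sweep independently with p_e(d) = 1 − exp(−α d); non-escaped lineages
carry the founder allele, which is derived with the background probability
q, and escaped lineages re-draw binomially at q, marginalized over the
background SFS. The p_e-dependence factorizes, so site likelihoods come
from a precomputed table over 64 p_e values (log-interpolated), and α is
maximized on a log grid (default 64 points over 1e-8–1e-3 per bp) with
three golden-section refinements; grid points default to every 2 kb, sites
within 100 kb contribute, and the per-window score is the maximum over
grid points. CLR = 2·max(0, log CL_sweep − log CL_background).

Two numerical properties matter. First, each site's sweep likelihood mixes
in 5% of the background likelihood: near the swept site the pure model is
degenerate (at p_e = 0 it allows only counts 0 and n), so a single
model-incompatible site — an incomplete sweep's non-carriers, a
mispolarized allele — would otherwise contribute tens of negative
log-units and veto a true sweep. Second, because the binomial escape
formulation does not strictly nest the background model, the clamped CLR
is exactly 0 for essentially all neutral windows: the scan is conservative
under the null, and the empirical threshold (the 1−p quantile of windows
sampled without replacement across populations, outliers strictly above
it) inherits that conservatism. The calibration suite asserts the null
outlier fraction at the nominal p = 0.001 within a binomial interval.

**eQTL enrichment** follows the outlier-vs-background permutation design:
observed overlap of outlier regions with per-tissue eQTL positions against
the distribution over equal-sized subsets (drawn without replacement) of
the below-5th-centile background regions; t = (obs − mean)/SD, with an
outer loop yielding a t distribution per tissue. **Ancestry elevation**
flags genes whose mean local ancestry exceeds the genome-wide window mean
by more than 3 SD; local-ancestry inference itself is an input.

## Medical

The pLOF burden per population counts distinct pLOF sites segregating
(DAF > 0) — not allele dosage, matching a count of variants — within the
direct gene set, normalized by the indirect-set count. The observed
statistic is the squared Pearson correlation of the ratio with
per-population mortality. The null redraws |direct| genes (equal gene
count; "similar in data size" is read as count) from the annotated genes
outside the direct set, 1,000 times by default. Two significance summaries
are reported: the signed-rank Wilcoxon P of (null − observed), the
one-vs-distribution convention of the original analysis, which is
anti-conservative by construction (n_iter pseudo-replicates of a single
comparison); and a rank-based empirical P, (1 + #{null ≥ obs})/(1 + n),
which is uniform under the null and is what the calibration suite asserts.
A power caveat belongs here: with 8 populations the null R² distribution
is the generic R²-of-8-points law whose 97.5th percentile is ≈ 0.50, so a
true R² of 0.5 is detected above that percentile only about half the time
— percentile exceedance at this sample size cannot be a high-power test,
whatever the analysis machinery.

ClinVar burden counts pathogenic-allele dosages per individual with cohort
median/range and per-population variant frequencies (flagged common above
MAF 0.05); the ACMG panel summary counts carriers and alleles per panel
gene for reportable classes. Vignettes: HbS frequency excludes samples
flagged as affected homozygotes; the APOL1 risk genotype is ≥ 2 risk
alleles across G1 (rs73885319 alone; its partner SNP is in complete LD)
and G2, treating the loci as mutually exclusive haplotypes; G6PD A−
accounting is X-aware (male hemizygotes contribute one allele); the
HLA-B\*57:01 vignette reports the proxy-SNP allele frequency. A vignette
site absent from the data reports missing, never zero.

## Structure

Great-circle distances use the Vincenty inverse geodesic on WGS84 (the
convention of the geodesic routine the original workflow used); the
non-convergent near-antipodal case falls back to the half meridian arc
2aE(e) ≈ 20,003.9 km, an error far below the geographic uncertainty of a
population centroid. The Procrustes test embeds both distance matrices by
classical PCoA (2 dimensions by default), computes t0 = sqrt(1 − D) after
centering, unit-trace scaling and the optimal rotation, and permutes the
population labels of the genetic matrix — implemented by permuting rows of
its embedding, which is exactly equivalent because PCoA commutes with a
simultaneous row/column permutation. P = (1 + #{t ≥ t0})/(1 + n_perm);
the default 1e5 permutations is scaled down from the original workflow's
1e7–1e9 for desk use and is configurable.

ROH detection reports maximal runs per sample satisfying all constraints
(≥ 100 SNVs, ≥ 1 SNV per 50 kb on average, ≤ 1 heterozygous and ≤ 5
missing calls, span ≥ 100 kb — the window size and SNV minimum are applied
as independent constraints), found by a two-pointer scan and verified
maximal by a post-hoc check in the suite. This replaces the original
tool's overlapping-window heuristic with an exact, deterministic criterion
over the same constraint set. When a tolerated heterozygote can sit at
either edge, overlapping maximal candidates arise; they are resolved
greedily left to right so calls are non-overlapping. Classes: A < 500 kb,
B 500 kb–1.5 Mb, C > 1.5 Mb. Per-sample inbreeding FHAT is the standard
(observed − expected homozygosity)/(n − expected) moment estimate.

## Pipeline and seeding

The pipeline derives one child stream per stage from the root seed via
`SeedSequence.spawn` with fixed stream indices, so requesting a subset of
stages or reordering them never changes another stage's randomness, and a
fixed config + seed reproduces every output byte for byte. The `afroscan`
command is a thin click wrapper over the same functions.

## Problem sizes in the test suite

The suite and the acceptance script run everything on simulated cohorts
sized for a single CPU: recovery loops use 4 populations × 24 samples on a
4-Mb chromosome with the CLR grid at 5 kb and 16 α values (the scan
defaults remain 2 kb/64); calibration batches pool ~3,600 10-kb windows
across 12 population-chromosomes; the f3 jackknife uses 400-kb blocks on
4-Mb chromosomes. These are the package's own desk-scale choices; the
statistics themselves carry no scale assumptions beyond window width.

## Known limitations

- The CLR null being degenerate at zero makes its empirical threshold
  conservative rather than exactly calibrated; on data with model-like
  signals the threshold behaves as intended.
- PiHAT uses no finite-sample allele-frequency corrections; with very few
  samples it is biased toward relatedness.
- The founder-mosaic LD model has a single decay scale; statistics
  sensitive to recombination-rate variation see none.
- X-linked handling is limited to the hemizygote accounting in the G6PD
  vignette; the QC cascade treats all sites as autosomal.
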