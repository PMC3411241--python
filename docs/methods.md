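# Methods

This note documents the statistical models implemented in `admixscan`, the
design of the synthetic-panel generator, the numerical choices that matter,
and what the test suite does and does not establish about real data.

## The analysis pipeline

### Diversity statistics

Molecular diversity per taxon group is summarized by Watterson's estimator
θ_W = S / (a_n · L), with S the number of sites segregating within the
group, L the sequenced length in bp, and a_n = Σ_{i=1}^{n−1} 1/i. Because a
predominantly selfing panel is genotyped as one consensus sequence per
accession, n is the number of accessions by default; outbred data can set
`sequences_per_accession=2` to count chromosomes. Minor allele frequencies
are alternate-allele dosage sums over twice the non-missing call count, and
the paper-style site filter retains sites with MAF *strictly* greater than
the threshold (default 5%). MAF spectra are computed within groups after the
overall-sample 5% pre-filter; shared/specific polymorphism classification
assigns each site the exact set of groups in which it segregates, a
partition of the polymorphic sites.

### Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete accessions. On fully homozygous data this equals the
haplotype-frequency r² = D²/(p_A p_a p_B p_b) identically, because each
selfed accession reads as a single haplotype carried twice; with residual
heterozygotes it is the standard genotypic approximation (this is where the
estimator can diverge from haplotype-EM implementations). Permutation
significance uses the add-one estimator (1 + #{r²_perm ≥ r²_obs})/(n_perm + 1)
with a mandatory seed. In `one_per_fragment` mode each sequenced fragment is
represented by the site with the greatest expected heterozygosity 2f(1−f),
leftmost on ties.

LD decay is modelled as

    E[r² | x] = a + b · exp(−c · x)

for inter-site distance x in cM or kb: r² near a + b at zero distance,
decaying to the asymptote a. The printed form of this regression in the
literature this package follows is typographically ambiguous between
exp(−c·x) and exp(−c/x); under the bounds used here (a ∈ [0,1], b ∈ [0,1.5],
c > 0) only the exp(−c·x) orientation is decreasing in distance and able to
fall from high short-range LD through r² ≈ 0.3 at 1 cM toward ≈ 0.1 at long
range, so that orientation is adopted everywhere (fitting, prediction,
simulation targets). Fitting is bounded nonlinear least squares with a
geometric multi-start grid on c (the non-convex axis); more starts can only
lower the residual SSE. Pairs at distance zero (sites within one fragment)
are excluded from fitting — the model carries no information at x = 0 —
but retained in LD tables. The physical-to-genetic hotspot scan reports
Δbp/ΔcM per consecutive marker interval and flags intervals under a caller
threshold; zero-ΔcM intervals are flagged unbounded rather than dropped.

### Structure and kinship

Ancestry is estimated under the standard admixture likelihood: individual i
draws each of its 2L allele copies from pool k with probability q_ik, pools
have frequencies p_kl, and genotypes are binomial with two trials. The
estimator is the classic EM (block relaxation on allele-copy pool
assignments); the complete-data log-likelihood is non-decreasing every
iteration and Q rows sum to one at every iterate. The log-likelihood omits
the constant binomial coefficient term. Convergence is relative ΔlogL below
`tol` (default 1e-6) or `max_iter` (500). This replaces Bayesian MCMC
structure software with a deterministic-given-seed ML fit of the same model
family; externally computed Q matrices can be imported as tsv and used
anywhere a Q matrix is accepted. For model-order choice, replicate
log-likelihoods from independently seeded restarts (local optima supply the
spread, an analogy to — not a replication of — MCMC run-to-run variance)
feed Evanno's ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K));
endpoints are undefined and a K with zero replicate variance is skipped with
a warning. Accessions are labelled admixed when no membership exceeds the
threshold (default Q > 0.8).

Kinship is the Ritland (1996) marker-based correlation estimator. Per
biallelic locus with panel frequency p and individual allelic proportions
x_i ∈ {0, ½, 1}:

    θ_ij(l) = x_i x_j / p + (1 − x_i)(1 − x_j) / (1 − p) − 1,

the m-allele form Σ_a x_ia x_ja / p_a − 1 over (m − 1) specialized to m = 2.
The multilocus estimate averages loci observed in both individuals
(weighting by m − 1 = 1 per locus); monomorphic markers are skipped with a
warning. Following mixed-model practice for selfed panels, negative entries
are clamped to 0 and the diagonal is overwritten to 2.0 (fully inbred:
1 + F = 2). Genotype PCA mean-imputes missing calls per site, orders axes by
variance, and fixes signs so each axis's largest-magnitude site loading is
positive.

### Phenotypes

Raw multi-year records are decomposed by fixed-effects ANOVA
value ~ accession + year with sequential (type-I) sums of squares,
accession first (type-II available for unbalanced designs). Broad-sense
heritability is h² = σ_g²/(σ_g² + σ_e²) with σ_g² = (MS_accession −
MS_residual)/divisor and σ_e² = MS_residual; negative σ_g² is reported raw
and clamped only inside h². The divisor defaults to the per-accession
replicate count (6 for two years × three harvests); the nonstandard divisor
used in the source analysis (n − 1 = 89) can be passed explicitly — its
derivation is unclear, so the package does not hard-code it. Adjusted means
are least-squares accession means averaged over year levels, which removes
year offsets under unbalance and reduces to raw means in balanced designs.
Fruit weight and locule number are log-transformed for analysis; trait
correlations are pairwise-complete Pearson.

### Association

Three nested models per marker:

* **GLM** — y ~ intercept + marker;
* **Q** — y ~ intercept + (K−1 membership columns) + marker (K−1 columns,
  not K, to avoid collinearity with the intercept);
* **K+Q (MLM)** — y = Xβ + m·α + u + ε with Var(u) = K σ_g², Var(ε) = I σ_e².

Variance components come from REML profiled over λ = σ_e²/σ_g² on the
spectral decomposition of K (grid search on log λ then bounded refinement);
eigenvalues pushed slightly negative by the diagonal/clamping adjustments
are clipped to zero with a warning. The marker is tested by a partial F
statistic with residual degrees of freedom on data whitened by V^(−1/2),
V = σ_g² K + σ_e² I. Because the whitening matrix is used only up to scale,
σ_g² = 0 reduces the test *exactly* to the ordinary GLM partial F test, and
with caller-fixed components the P value matches a Cholesky-whitened GLS
computation to machine precision. `per_marker_reml` (default) re-estimates
components under each marker-inclusive design; `p3d` estimates them once on
the no-marker model and reuses them across the scan (much faster, nearly
identical P values in practice).

Per scan (one trait × one model = one BH family): sites are MAF-filtered,
markers with one genotype class are skipped and counted, missing marker
calls are mean-imputed for the test statistic only (`n_used` reports
non-missing calls; class-mean effects use non-missing calls). Marker R² is
the Q-model partial R² = (RSS_reduced − RSS_full)/TSS. Allele effects are
reported on the raw trait scale as the difference of homozygote class means,
signed so a named reference accession's allele class is the baseline; the
standardized effect divides the analysis-scale class-mean difference by the
trait standard deviation, heterozygotes excluded. BH adjustment is the
step-up procedure (via statsmodels), with the two conventional significance
presets (adjusted P < 0.005 and < 0.05) surfaced as labelled columns. The
calibration diagnostic compares each model's raw-P ECDF against the uniform
diagonal and ranks models by the KS-type maximum deviation.

## The synthetic-panel generator

The generator reproduces, with tunable knobs, the statistical structure of a
~90-accession selfing-crop core collection on one chromosome: a wild group,
a cultivated group, and a large admixed group between them.

**Frequencies.** Two ancestral pools draw per-site frequencies from the
Balding–Nichols law around an ancestral frequency p ~ U[0.05, 0.95]:
Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k). The drift is split asymmetrically,
F_wild = 0.25·fst and F_cultivated = 1.75·fst, keeping pairwise
differentiation at fst (the ratio-of-expectations Hudson-type FST equals the
mean of the two) while letting the bottlenecked crop pool drift more — which
is what domestication does, and what stabilizes the diversity gradient. The
cultivated pool additionally loses a fraction (1 − bottleneck_keep) of sites
to fixation. When sites carry map positions, all uniform/Beta deviates are
drawn through a Gaussian copula with inter-site correlation
exp(−freq_coherence_rate · d): marginals are exactly Balding–Nichols, but
neighbouring sites get similar frequencies. This matters because r² between
two sites is bounded by their frequency mismatch; without the coherence that
shared genealogy produces in real data, near-zero-distance pairs could not
reach high r² and no parameter setting would reproduce the observed decay
curve.

**Haplotypes.** Per pool, founder haplotypes are thresholded Gaussian AR
chains (correlation exp(−switch_rate·d)), so the founder panel itself
carries decaying LD. Each sampled haplotype mosaics over founders
Li–Stephens-style, switching founder with probability 1 − exp(−switch_rate·d)
per gap and redrawing its source pool from the individual's ancestry q at
each switch. Ancestry is q = 0 for wild, q = 1 for cultivated, and
q ~ Beta(0.5, 0.5) for the admixed group — the U-shaped law puts roughly 26
of 63 admixed accessions below the Q > 0.8 clustering rule, matching the
panel the generator emulates. Two cultivated accessions carry residual wild
introgression (q = 0.8), the mechanism behind the singleton excess observed
inside crop germplasm.

**Selfing.** Each heterozygous call resolves to a homozygote with
probability 1 − (1/2)^g after g selfing generations. The *direction* of
resolution follows a per-individual Markov haplotype choice along the map
(switching at the mosaic rate): marginally a fair coin per site, but linked
sites co-resolve as they do under real selfing. Resolving sites
independently instead would erase most short-range LD in admixed
individuals — an early design that measurably flattened the decay curve and
was replaced. Tract lengths are still not genealogical; the generator is
explicitly not an identity-by-descent simulator.

**Physical map.** bp positions integrate a piecewise kb/cM profile
(default 750 kb/cM with a planted 20 kb/cM hotspot segment at 85–87 cM) so
the hotspot scan has a true positive; sites within a fragment share a cM
position and are offset by ~100 bp steps.

**Phenotypes.** Analysis-scale trait values are
y = μ + Σ β·dosage + s·q + polygenic background + year effect + residual,
with the residual variance set so realized broad-sense h² matches
`target_h2` (default 0.95). Fruit weight and locule number are generated on
the log scale and stored as exp(y), so the pipeline's log transform recovers
exact linearity; their QTL effects are therefore in log units. The soluble
solids trait shares a QTL site with fruit weight (opposite signs) and its
polygenic background correlates −0.7 with fruit weight's, reproducing the
strong negative FW–SSC correlation of such panels. Structure effects
(s = +0.61 log-g, +0.25 log-locules, −1.04 °Brix per unit cultivated
ancestry) were chosen so structure explains roughly 24% / 5% / 12% of the
three traits' variance.

**Calibration of the paper-like preset.** switch_rate = 0.15/cM and
freq_coherence_rate = 0.14/cM were calibrated once so the fitted decay curve
crosses r² = 0.3 near 1 cM (mean ≈ 1.1 cM, sd ≈ 0.4 over seeds) on the
admixed subset; the locule-number QTL effect (0.295 log-locules per allele
copy at a site fixed at frequency 0.5 in both pools) was calibrated so its
realized marker R² centres on 0.44, the largest single-marker effect such a
panel exhibits. These are frozen defaults, not fitted per run.

**Determinism.** Everything derives from one numpy PCG64 generator seeded by
`SimConfig.seed`; identical configs give bit-identical output. The pipeline
fans a global seed out to stages via SHA-256 of the stage name.

## What the benchmarks do and do not show

The property suite (`tests/test_acceptance.py`, reproducible via
`scripts/acceptance.py`) checks: exact agreement of the r² estimator with
haplotype counting on homozygous data; exact agreement of the mixed-model
test with a GLS oracle and its reduction to the GLM; BH against a literal
step-up implementation; decay-parameter recovery within 10% under known
noise; type-I calibration of K+Q (within [0.03, 0.07] at nominal 5%) versus
naive-GLM inflation (> 0.10) under a structure-confounded null; ≥ 90% power
for the planted R² ≈ 0.44 QTL at BH-adjusted P < 0.005; Evanno choosing
K = 2 for two-pool panels; and Watterson's θ within 5% of the scaled
mutation rate configured in an independent neutral coalescent simulation
(msprime), plus the wild > admixed > cultivated ordering. Problem sizes
(e.g. 200 null replicates, 100 power panels, 20 Evanno meta-runs) were
chosen as the smallest giving stable Monte-Carlo estimates at the stated
tolerances.

Because the generator is copying-based and calibrated, these results
demonstrate correctness and calibration of the *estimators and tests*, not
realism of tomato demography: selection, genealogical tract lengths,
genotyping error and ascertainment are all absent. Numbers obtained on real
panels will differ; the pipeline's contracts (filters, estimators,
corrections) are what carries over.

## Known limitations

- Genotypic r² diverges from haplotype-EM LD estimators when residual
  heterozygosity is substantial.
- The admixture EM assumes binomial sampling of two independent allele
  copies; on fully selfed genotypes the two copies are identical, so the
  likelihood is overconfident and intermediate ancestries are pushed
  slightly toward 0/1. Group assignment and ΔK model choice are unaffected
  in the tested regimes.
- Evanno's ΔK cannot evaluate the endpoints of the K range and is undefined
  when replicate likelihoods collapse to one optimum.
- The REML profile assumes a single random effect with covariance
  proportional to K; no multi-kernel or spatial terms.
- The two-factor ANOVA is fixed-effects; no REML heritability, no field
  spatial correction.
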