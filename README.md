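# admixscan

Diversity, linkage-disequilibrium and structure/kinship-corrected
association mapping for admixed, predominantly selfing crop panels — with a
synthetic-panel generator so the entire pipeline runs and is tested without
any external data.

## The problem

Inbred crops such as cultivated tomato are poor material for genome-wide
association: domestication bottlenecks leave little molecular polymorphism,
and selfing inflates linkage disequilibrium so that associations cannot be
localized. Panels that mix the crop, its wild relative and a large admixed
intermediate group (cherry-type tomato between *S. lycopersicum* and
*S. pimpinellifolium* is the canonical case) recover both diversity and
mapping resolution — at the price of strong population structure that
confounds naive marker–trait tests. `admixscan` implements the full
analysis such a panel needs:

* **Diversity** — Watterson's θ_W = S/(a_n·L) per taxon group, MAF spectra,
  per-kb polymorphism rates by coding/noncoding class, shared/specific
  polymorphism classification, strict MAF > 5% site filtering.
* **LD** — pairwise r² (squared dosage correlation, identical to haplotype
  D²/(p_A p_a p_B p_b) on homozygous data), permutation P values, nonlinear
  decay regression **y = a + b·e^(−c·x)** over genetic or physical distance,
  and a kb/cM recombination-hotspot scan.
* **Structure & kinship** — maximum-likelihood admixture estimation (EM on
  the binomial admixture model; `AdmixtureModel`), Evanno's ΔK for the
  number of subpopulations, Q > 0.8 admixture classification, Ritland
  marker kinship with the mixed-model adjustments (negatives clamped,
  diagonal 2.0; `RitlandKinship`), genotype PCA.
* **Phenotypes** — two-factor ANOVA (accession + year), broad-sense
  heritability (MS_c − MS_e)/divisor, year-adjusted accession means, log
  transforms, trait correlations.
* **Association** — naive GLM, structured Q model, and the K+Q mixed model
  y = Xβ + m·α + u + ε with Var(u) = Kσ_g² (REML via spectral decomposition,
  partial-F marker tests, per-marker or P3D variance components),
  Benjamini–Hochberg FDR per scan, marker R² from the Q model, allele
  effects anchored to a reference accession, and the P-value-CDF
  calibration diagnostic that ranks models by how well they correct
  structure confounding.

Model-shaped components are scikit-learn style estimators
(`LDDecayModel`, `AdmixtureModel`, `RitlandKinship`, `GenotypePCA`,
`AssociationScan`) with `fit`/`predict`/`transform`, `get_params`, and
fitted attributes ending in `_`; everything else is plain functions.

## Worked example

```python
import numpy as np
from admixscan import (make_fixture, filter_by_maf, watterson_theta,
                       ld_matrix, fit_ld_decay, estimate_admixture,
                       ritland_kinship, adjusted_means, run_scan,
                       classify_admixed)

panel = make_fixture("paper_like", seed=1)   # 90 accessions, ~350 sites
g = panel.genotypes

for grp in ("pimpinellifolium", "cerasiforme", "esculentum"):
    theta, s = watterson_theta(g, grp, total_length=44223)
    print(f"theta_w({grp}) = {theta:.2e}  (S = {s})")

gf = filter_by_maf(g, 0.05)
pairs = ld_matrix(g, subset="cerasiforme", maf_threshold=0.05)
fit = fit_ld_decay(pairs[pairs["d_cm"] > 0], "cM")
print(f"decay fit: a={fit.a:.3f} b={fit.b:.3f} c={fit.c:.3f}; "
      f"r2 at 1 cM = {fit.a + fit.b * np.exp(-fit.c):.3f}")

q = estimate_admixture(gf, K=2, seed=11)
kin = ritland_kinship(gf)
means = adjusted_means(panel.phenotypes, "LCN")
scan = run_scan(g, means, "LCN", model="KQ", q=q, kinship=kin,
                mlm_method="p3d")
print(scan.nsmallest(3, "p_value")[["site_id", "p_value", "p_adjusted",
                                    "r2_marker", "maf"]].to_string(index=False))
```

prints

```
theta_w(pimpinellifolium) = 2.41e-03  (S = 301)
theta_w(cerasiforme) = 1.57e-03  (S = 328)
theta_w(esculentum) = 9.83e-04  (S = 147)
decay fit: a=0.029 b=0.563 c=1.084; r2 at 1 cM = 0.220
  site_id      p_value   p_adjusted  r2_marker      maf
TD044-381 5.423553e-12 1.724690e-09   0.485224 0.454545
 TD040-84 9.965072e-05 1.116091e-02   0.205892 0.303371
TD039-132 1.052916e-04 1.116091e-02   0.198644 0.247191
```

Reading the output: molecular diversity falls from the wild group through
the admixed group to the cultivated group (the hallmark of a domestication
bottleneck softened by admixture); the fitted LD decay drops below
r² = 0.3 within about a centimorgan on this seed's panel; and the K+Q scan
puts the planted large-effect locule-number QTL (`TD044-381`, marker
R² ≈ 0.49 here) far ahead of the genome-wide background at BH-adjusted
P ≈ 2 × 10⁻⁹, while the next hits are an order of magnitude weaker.

The same pipeline runs from the shell:

```bash
admixscan simulate --preset paper_like --seed 1 --outdir panel/
admixscan all --preset paper_like --seed 1 --outdir run/   # full pipeline + manifest
admixscan assoc --genotypes panel/genotypes.tsv \
    --phenotypes panel/phenotypes_raw.tsv --trait LCN --model kq \
    --maf 0.05 --seed 7 --out lcn_scan.tsv
```

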