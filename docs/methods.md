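# Methods

## The weighted burden model

For a gene with qualifying rare variants (MAF ≤ f_max, default 0.01) the
per-individual burden for score column *s* is

    B_i = sum_j d_ij * w(f_j) * s_j

with ALT-dosage d_ij ∈ {0, 1, 2}, allele-frequency weight w, and s_j either
a category indicator (LOF or protein-altering) or a predictor score.
Missing genotypes count as homozygous reference (the conservative burden
convention) and are tallied per gene; a variant lacking a predictor's score
contributes 0 to that predictor's burden, so LOF variants — which missense
predictors do not score — still leave every individual with a defined total.

Case status is then modelled by logistic regression,

    logit P(y_i = 1) = a + c'x_i + b_L * LOF_i + b_P * PA_i + b * B_i

where x_i holds sex and 20 principal components. The Wald statistic
z = b̂/se(b̂) gives a two-sided normal p-value, reported as the signed log
p-value SLP = sign(b̂)·(−log10 p). A likelihood-ratio p is available as a
cross-check (`fit(method="lr")`). Genes where damaging variants are
protective are analysed with the complemented outcome ("being a control"),
so a useful predictor always earns a positive SLP.

### Weight curve

The default weight is linear, w(f) = 1 + (w_max − 1)(1 − f/f_max) with
w_max = 10: w(0) = 10, w(f_max) = 1, monotone non-increasing. The exact
functional form used by legacy burden-testing software is not fully
standardised, so the curve is pluggable ("step" and "logistic" alternatives)
and the configuration is recorded in every output's metadata. All results
here use the linear form. Weights are computed from the same MAF used for
the rarity filter (the annotation-table MAF by default; cohort allele
frequencies otherwise).

### Numerical choices

* Fits use statsmodels' Newton maximum likelihood (tol 1e-10, ≤ 100
  iterations); non-convergence is flagged and the SLP withheld unless
  explicitly permitted.
* The outcome is canonicalised before fitting (the minority class is
  modelled; coefficient signs are restored afterwards). This makes fits of
  an outcome and its complement follow identical arithmetic, so outcome
  complementation negates every SLP *exactly*, not merely to solver
  tolerance.
* Exactly collinear design columns are dropped left-to-right with a
  warning and recorded in the results (`dropped_terms`).
* A zero-variance predictor burden carries no information: SLP = 0 with a
  `degenerate` flag, not an error.
* |SLP| is capped at 323 (the −log10 of the smallest positive double) with
  a `capped` flag; β = 0 exactly (measure zero) yields SLP = 0 since the
  sign convention is undefined there.
* Score correlations are Pearson by default (most inputs are rank scores,
  so Spearman — available by flag — is close); missing scores are handled
  pairwise-complete, and pairs with fewer than 3 shared variants are left
  absent. The method used is recorded in output metadata.
* Relative SLPs divide each gene's column by its best *positive* SLP (that
  cell maps to exactly 1); an all-non-positive column has no reference
  point and is emitted absent with a flag.

### Category rules

LOF: stop_gained, frameshift_variant, splice_acceptor_variant,
splice_donor_variant. Protein-altering: protein_altering_variant,
missense_variant, start_lost, stop_lost. Plain-text synonyms ("essential
splice site", "stop gained", ...) are accepted. The categories are enforced
as mutually exclusive; a variant with several transcript-level terms takes
the most severe (LOF > protein-altering > other). Unrecognized terms are
excluded with a warning and counted in a run report rather than failing the
run.

## The synthetic cohort generator

Real studies of this design use restricted biobank exomes at n ≈ 470,000.
The generator emulates the *statistical structure* of such data at desk
scale; its defaults define the study conditions used throughout the tests:

* **MAF law**: log-uniform on [1/(2n), f_max] — heavy excess of very rare
  alleles like a rare-variant site-frequency spectrum, without
  population-genetic machinery.
* **Categories**: (LOF, protein-altering, excluded) with probabilities
  (0.10, 0.60, 0.30), roughly the mix seen among annotated rare exome
  variants once synonymous and non-coding calls are set aside.
* **Latent truth**: per-variant true pathogenicity in [0, 1]; Beta(9, 1)
  for LOF (nearly all damaging), Uniform(0, 1) for protein-altering
  (missense spans benign to pathogenic), Beta(1, 9) for excluded.
* **Predictor panel**: each predictor reports the quantile rank of
  λ·truth + (1 − λ)·noise across scored variants (protein-altering only by
  default). λ = 1 is a perfect rank predictor, λ = 0 pure noise. Noise
  streams are keyed by λ, so equal-λ predictors are bit-identical — a
  deliberate reproducibility property, not an attempt at realism.
* **Genotypes**: independent Binomial(2, MAF) per site (linkage
  equilibrium). Burden statistics sum within a gene, so LD is not modelled.
* **Covariates**: sex ~ Bernoulli(0.5) with default log-OR 0.2; 20 PCs are
  pure standard normals — they exercise the covariate plumbing, they do not
  model population structure.
* **Phenotype**: logit-linear in the frequency-weighted *true* burden
  (effect_size default 0.25 log-odds per unit, a moderately powered gene at
  n = 10,000), with the intercept solved by Brent root-finding so the
  expected prevalence equals the target (default 0.20, typical of common
  cardiometabolic phenotypes) to within 1e-6.
* **Seeding**: one master seed expands into five named child streams
  (variants, panel, genotypes, covariates, phenotype); identical
  configurations are bit-reproducible.

Because the generator omits LD, relatedness, genotyping error, population
stratification and realistic gene length/constraint variation, passing
tests demonstrate the *statistical correctness* of the pipeline — null
calibration, power ordering in predictor informativeness, unbiased effect
recovery, exact symmetries — not performance claims about any real
predictor on real exomes.

## Test and script problem sizes

The simulation checks run at sizes chosen to make their statistical
assertions sharp while keeping the suite quick: null calibration uses 2,000
replicates of a 5,000 × 100 gene (the hit rate at |SLP| ≥ 1.301 is compared
with the exact binomial 99% interval around 0.05); power ordering uses 10
genes at n = 10,000 with λ ∈ {0.9, 0.3, 0.0}; effect recovery uses 100
replicates at n = 20,000 with 2-SE coverage required in ≥ 90. The
acceptance script reruns scaled variants of these (500 null replicates at
n = 2,000; 6 genes; 50 recovery replicates at n = 10,000) plus the
published-table row means.

## Known limitations

* The Wald p relies on the normal approximation; with very few carriers or
  quasi-separation it can misbehave — such fits are flagged rather than
  corrected (no Firth/penalised fallback).
* Single-predictor-at-a-time testing mirrors the benchmark design; no
  multiple-testing adjustment is applied, and none is implied.
* The VCF reader ingests GT fields only (no dosage/GP fields, no BGEN or
  PLINK formats).
* Relative SLP scaling is undefined for genes where no predictor achieves a
  positive SLP; those columns are flagged absent by design.
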