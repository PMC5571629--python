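# Methods

This note records the statistical models, conventions and design choices
behind `focaltax`, and what the synthetic-data studies do and do not
demonstrate.

## Zero-inflated count model

Focal-taxon read counts in 16S surveys are sparse (often >60% zeros) and
overdispersed. The package models them as a two-component mixture: a
logistic regression for structural zeros and a negative-binomial (NB2)
regression for counts,

    logit(π_i) = x_i'γ + log T_i
    log(μ_i)   = x_i'β + log T_i
    P(y=0)   = π + (1−π)·f(0; μ, k)
    P(y=y>0) = (1−π)·f(y; μ, k),   Var(y | count component) = μ + μ²/k.

The log of the per-sample total read count T enters **both** linear
predictors as an offset with coefficient fixed at 1, so the model
describes proportions rather than counts. The zero-inflated Poisson (ZIP)
is the k→∞ member; plain NB/Poisson (no inflation) are available for
univariate screens and closed-form checks.

**Fitting.** Direct joint maximum likelihood with analytic gradients
(L-BFGS-B), dispersion parameterized as log k for unconstrained
optimization, two starting points (a null start from marginal moments and
a two-stage start from a logistic fit of the zero indicator plus a
Poisson fit on positives); the better final likelihood wins. An EM
formulation would be equally valid; direct MLE was chosen for simplicity
and speed (a 7-parameter fit at n = 5000 takes ~0.2 s). Wald standard
errors come from the inverse central-difference Hessian at the optimum.
Convergence is monitored by the max-norm of the gradient
(‖g‖∞/n < 10⁻⁵ in the test suite). The LRT between ZINB and ZIP places
the restriction (1/k = 0) on the boundary of the parameter space, so the
χ²₁ reference is conservative; this is reported, not corrected.

**Design matrices.** Categorical covariates are dummy-coded against
stated reference levels; missing values form a hidden "missing" level so
that incomplete records still contribute. The hidden-category device
applies only to categorical covariates: rows missing a continuous
covariate (age) are excluded from multivariate fits. Unobserved levels
are dropped with a warning.

**Univariate screen.** Each candidate covariate is fitted alone in (a) a
logistic regression of presence and (b) a plain NB regression of counts
on all samples, both with the log-depth offset; a candidate enters the
multivariate model when any non-reference level reaches p < 0.1 in either
model, and age/sex/race are always retained as baseline covariates.
Fitting the NB screen on all samples (zeros included) is an
interpretation choice — a positives-only variant sits behind
`positives_only_nb=True`. Under the null the union-of-two-tests selection
rate is ≈10–20% (the two tests are correlated, having the same data), as
the calibration test verifies empirically.

**APV.** The overall fitted mean proportion for level L of a covariate
sets every sample's covariate to L, predicts the unconditional mean
E[y] = (1−π)μ, averages over samples, and divides by the mean total read
count; reported as a percentage. For an intercept-only, no-inflation
Poisson fit this reduces exactly to Σy/ΣT, which the tests assert to
1e-8.

## Screening conventions

* Presence threshold is 1 read (configurable).
* Sample filtering keeps samples with depth ≥ 10,000 (boundary
  inclusive) from the requested body site, then represents each subject
  by the earliest retained specimen. The operation is idempotent.
* Overlap significance is the hypergeometric upper tail
  P(X ≥ observed | N, |A|, |B|) — the standard behind the overlap-
  statistics web services; verified against exhaustive enumeration for
  small universes.
* Geometric-mean relative abundance is computed over detected samples
  only, and reported as undefined (NaN), never 0, for undetected taxa.
* Mann–Whitney tests use exact enumeration of group assignments (ties
  handled by mid-ranks) when the combined n ≤ 12, and the tie-corrected
  normal approximation otherwise. Longitudinal groups partition
  multi-sample subjects into never / intermittently / always positive;
  abundance in groups II vs III is compared one-sidedly among positive
  samples, with a two-sided depth check guarding against sequencing-depth
  confounding.

## Diversity conventions

Shannon is log base 2 (QIIME-1 convention); Chao1 uses S + F1²/(2F2)
with the bias-corrected S + F1(F1−1)/(2(F2+1)) when F2 = 0; Faith PD
includes the branch path to the root (rooted convention; computed via
scikit-bio). Rarefaction is a multivariate-hypergeometric subsample
(exactly without replacement, depth preserved); samples shallower than
the requested depth are flagged and excluded, not errors. Unweighted
UniFrac and Bray–Curtis (on counts, unrarefied unless a depth is
configured) come from scikit-bio/SciPy; PCoA is classical scaling
implemented directly so that negative eigenvalues are reported rather
than dropped. PERMANOVA is one-factor, with p = (#{F* ≥ F} + 1)/(B + 1);
permutation t-tests use the Welch statistic (pooled-variance behind a
flag), 999 Monte-Carlo permutations by default (p floor 1/1000), and
Bonferroni correction over the pairwise comparisons in a panel.

## Compositional network inference

Counts are aggregated to species, filtered at ≥20% prevalence (boundary
inclusive), pseudocounted (+1, the SPIEC-EASI convention) and CLR-
transformed. Neighborhood selection regresses each standardized CLR
column on the rest with an L1 penalty; the penalty grid is log-spaced
over [λ_max·0.2, λ_max] with λ_max the largest absolute off-diagonal CLR
correlation, so λ ≥ λ_max gives an empty graph. Edges use the union
("or") rule; signs come from the mean of the two directional
coefficients (the larger-magnitude coefficient breaks exact ties).

StARS draws rep_num = 20 subsamples of size ⌊10√n⌋ without replacement,
computes per-edge selection frequencies θ_e(λ), defines instability
D(λ) as the mean of 2θ(1−θ) over node pairs, monotonizes D from the
sparse end, and selects the densest λ with D̄ ≤ β = 0.05. When no λ
meets the stability target the sparsest model is returned with a warning
— the conservative fallback used by the reference implementations.
Plain StARS is implemented; bounded/early-stopping variants select the
same λ and are treated as optimizations.

**CLR degeneracy.** CLR rows sum to zero exactly, so each column is an
exact linear combination of the others. At small p this makes a dense
all-negative regression fit cheap and *stable*, and it makes the
marginal CLR correlations of even independent taxa ≈ −1/(p−1). The
pipeline is therefore validated at p ≈ 24–30, where the conditional-
dependence signal dominates the compositional artifact; at p ≲ 10 the
selected models are legitimately near-empty (the sparse end flickers and
the stability target is never met). This is a property of CLR-based
neighborhood selection generally, not of this implementation.

## Resilience

Centralities are computed on the unweighted selected network (signs are
an edge attribute, ignored for topology): degree/(N−1) and betweenness
normalized by (N−1)(N−2)/2. Natural connectivity is reported in two
modes because the index circulates in inconsistent notation: `standard`
= ln((1/N)Σe^{λᵢ})/(N − ln N) (an edgeless graph scores exactly 0) and
`literal` = ln(Σe^{λᵢ})/(N − ln N). Comparisons must hold the mode
fixed; `standard` is the default everywhere. Σe^{λᵢ} is checked against
the trace of the matrix exponential to 1e-8.

Attack simulations remove the current-maximum node (degree or
betweenness, recomputed adaptively after each removal by default;
initial-ranking variant behind `adaptive=False`; lexicographic label
breaks ties for determinism) or a uniform random node, recording natural
connectivity for remaining sizes N … 1. Connectivity distributions rerun
the full network-inference pipeline per subsample per condition
(presence/absence of a condition taxon, which is itself excluded from
the inferred network) and compare the two distributions with a one-sided
Mann–Whitney test. Control taxa are matched on detection rate (30–40%)
and geometric-mean nonzero relative abundance (10⁻³–10⁻²) by default.

## Synthetic cohorts

The generator emulates a crowd-sourced gut survey: subjects provide 1–5
samples (~4% multi-sample), covariates (age, sex, race, BMI category,
antibiotic history, country) are subject-level with realistic missing
rates, depths are log-normal with median 20,000 reads (so the
≥10,000-read filter removes a nontrivial ~10%), focal counts follow the
ZINB above (the generator and the fitted model share their functional
form by construction), and the background community is logistic-normal-
multinomial: latent log-abundances from a multivariate normal whose
precision matrix carries a known sparse graph, softmax to proportions,
multinomial at each sample's depth. Co-detection of focal OTUs is driven
by a shared latent Bernoulli(0.5) factor that adds a log-odds boost
("coupling", default 2) to both detection logits. Missingness is
injected after count generation, so observed-data gaps never perturb the
generative truth.

Ready-made precision matrices: `chain_precision` (tridiagonal) and
`hub_precision`, the latter a union of star motifs (default 5 hubs × 5
spokes at p = 30) because a single hub of degree p−1 cannot carry
partial correlations strong enough to remain positive definite.

**What the generator does not emulate:** real taxonomies, sequencing
error and chimeras, batch effects, covariate–community dependence, or
within-subject autocorrelation of repeat samples. Passing tests
demonstrate the *methods* are correctly implemented and calibrated under
their own assumptions; they do not certify conclusions about any real
cohort.

## Problem sizes and numerical choices

Simulation studies run at desk scale chosen to keep the full suite fast
while leaving comfortable signal margins: ZINB recovery and model
comparison at n = 5000 (100 replicates); network recovery at p = 30,
n = 1000 with a 20-point penalty path (the 100-point path of the
production default changes selection negligibly on these graphs); noise
control at p = 10, n = 500; null calibrations with 200 replicates of
199-permutation tests; the planted connectivity study at p = 24 with 20
iterations of 200-sample inference per condition, where the
focal-positive condition carries a full chain and the negative condition
a half-density matching of equal edge strength. Optimizer tolerances:
L-BFGS-B ftol 1e-12 / gtol 1e-7; linear predictors clipped at ±700
before exponentiation; log k bounded in [−20, 30]; λ grids strictly
decreasing; CLR standardization uses population (ddof = 0) scaling.

## Known limitations

* Wald p-values per dummy level without multiplicity correction, by
  design; treat borderline levels with care.
* The logistic offset is taken literally (coefficient 1 on log T in the
  zero component), which makes structural-zero probability *increase*
  with depth under positive coefficients — a modelling convention
  inherited from treating both components as proportion models.
* Repeated measures are handled by first-specimen deduplication, not
  mixed models.
* StARS instability estimates share subsamples across λ, so selected
  networks can vary between seeds near the stability boundary.
* BIOM support covers the v1 JSON format only (dense or sparse), not
  HDF5 v2.1.
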