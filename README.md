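# focaltax

A toolkit for taxon-centric ecology of the human gut microbiome in
large 16S amplicon surveys.  Given a count table, per-sample metadata and
a phylogeny, it answers the questions one asks about a *focal* bacterial
taxon — a low-abundance organism of clinical interest such as the
oxalate-degrading gut commensal *Oxalobacter formigenes*:

* **Screening** — depth/site/repeat-specimen filtering, presence calls,
  prevalence and geometric-mean relative-abundance summaries,
  hypergeometric co-occurrence tests, one-sided Mann–Whitney
  abundance-shift tests, and longitudinal colonization grouping for
  subjects with repeat samples.
* **Host-feature modelling** — a zero-inflated negative-binomial (ZINB)
  regression of focal-taxon counts with the log total read count as an
  offset in *both* components, so the model describes proportions:

      logit(π_i) = x_i'γ + log T_i        (structural zeros)
      log(μ_i)   = x_i'β + log T_i        (NB counts, Var = μ + μ²/k)

  with a univariate p<0.1 screen, a hidden "missing" category per
  categorical covariate, ZINB-vs-ZIP comparison by AIC/BIC/LRT, and
  average-predicted-value (APV) fitted mean proportions.
* **Diversity** — rarefaction, Faith PD / Chao1 / Shannon (bits) /
  observed richness, unweighted UniFrac and Bray–Curtis distances, PCoA,
  one-factor PERMANOVA and intra/inter-group distance comparison.
* **Network inference** — SPIEC-EASI-style compositional networks:
  species aggregation, ≥20% prevalence filter, centered log-ratio
  transform, Meinshausen–Bühlmann neighborhood selection over a penalty
  path, StARS stability selection (β = 0.05), signed edges from the
  averaged coefficient matrix.
* **Resilience** — normalized degree/betweenness centralities, natural
  connectivity ln(Σe^{λᵢ}/N)/(N − ln N), sequential-attack simulations,
  and presence/absence natural-connectivity distributions with matched
  control taxa.
* **Synthetic cohorts** — a generator producing AGP-style cohorts with
  known ground truth (ZINB focal counts, logistic-normal-multinomial
  communities over a known conditional-dependence graph, random
  phylogenies, longitudinal sampling, missing covariates), so every stage
  is testable without external downloads.

## Worked example

Run the full pipeline on a synthetic cohort:

```bash
focaltax pipeline --out run1 --seed 3
```

which prints the stage statuses and writes `run1/summary.txt`, e.g.:

```
screening: kept 346 samples; focal overlap p = 9.99e-06
zinb: AIC 1502.7 vs ZIP 2203.2; LRT p = 8.34e-155
diversity: PERMANOVA pseudo-F 1.27, p = 0.0839
netinfer: 41 edges at lambda = 0.1720
resilience: baseline connectivity 0.0234
```

Reading: after the ≥10,000-read / fecal-site / first-specimen filter, 346
of the generated samples remain; the two focal OTUs co-occur far more
often than chance (hypergeometric overlap p ≈ 10⁻⁵); the ZINB fits the
zero-heavy focal counts much better than the zero-inflated Poisson
(ΔAIC ≈ −700); community composition differs modestly by the number of
focal OTUs detected; and the inferred species network (41 edges here,
against a 39-edge generating chain) has a baseline natural connectivity
of 0.023 that the resilience stage then stresses with degree-,
betweenness- and random-ordered node removal.

Per-stage artifacts (`focal_summary.tsv`, `zinb_coefficients.tsv`,
`alpha_diversity.tsv`, `network_edges.tsv`, `attack_*.tsv`,
`manifest.json`, ...) land in the output directory; a rerun with the same
seed reproduces them exactly.

The same stages are available as a library — see `focaltax.screening`,
`focaltax.zinb`, `focaltax.diversity`, `focaltax.netinfer`,
`focaltax.resilience`, `focaltax.markers`, `focaltax.synthetic` — and
`docs/methods.md` for the statistical conventions.

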