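# gshcohort

Bayesian and frequentist analysis of two-group brain-metabolite cohorts —
built for studies that ask whether a spectroscopy-measured metabolite
(here glutathione, GSH, in mM) tracks clinical functioning in a clinical
high-risk (CHR) group versus healthy controls (HC).

The package provides, as a tested library:

* **Cohort I/O and QC** — a validated CSV schema (id, group, GSH, CRLB,
  SOFAS, SOPS, CAST, AUDIT-C, age, gender) and the CRLB < 30% inclusion
  filter applied before every statistic.
* **Bayesian Spearman correlation** — rank data treated as the degraded
  image of latent bivariate-normal scores; Metropolis-within-Gibbs over
  the truncated latent scores and ρ ~ Uniform[−1, 1]; reported as the
  posterior mode, 95% highest density interval (HDI), posterior
  proportion (PP) and the Savage–Dickey Bayes factor
  BF₁₀ = p(ρ=0 | prior)/p(ρ=0 | posterior).
* **Hierarchical group GLMs** — y_i = β0 + β_group(i) (+ β_sofas·x_i) + ε_i
  with data-scaled priors: β0 ~ N(mean, (5·SD)²), deflections
  β_group ~ N(0, σ_β²) with σ_β ~ Gamma(SD/2, 2·SD) so the groups shrink
  each other, σ_i ~ Uniform(SD/1000, 1000·SD). Deflections are
  sum-to-zero (exact ±d per draw); the group contrast and its effect size
  (difference / σ_i) are full posteriors.
* **Frequentist replication** — Pearson chi-squared (no continuity
  correction), pooled/Welch t-tests, classical Spearman, two-step
  hierarchical regression with the R²-change F test, median split, and
  one-way ANOVA with Tukey HSD.
* **Synthetic cohorts** — a Gaussian-copula generator reproducing the
  published group sizes, marginals, CRLB moments and within-group
  GSH–SOFAS rank-correlation targets, so the whole chain is testable
  without the unavailable raw data.
* **Pipeline** — `run_full_analysis` chains all of the above with
  per-stage seeds; identical seeds give byte-identical reports. A thin
  CLI (`gshcohort simulate|correlate|compare-groups|freq-suite|run`)
  wraps the same functions.

See `docs/methods.md` for the models, priors and numerical choices, and
`examples/` for one short script per capability.

## Worked example

```python
from gshcohort import (bayesian_spearman, default_config, filter_by_crlb,
                       generate_cohort)

cohort = filter_by_crlb(generate_cohort(default_config(seed=7)))
chr_group = cohort.select("CHR")
res = bayesian_spearman(chr_group.values("gsh"), chr_group.values("sofas"),
                        n_kept=4000, thin=2, burn_in=500, seed=7)
s = res.rho_summary
print(f"rho mode {s.mode:.2f}, 95% HDI ({s.hdi_low:.2f}, {s.hdi_high:.2f}), "
      f"PP {s.pp:.2f}, BF10 {res.bf10:.2f}")
```

prints

```
rho mode 0.82, 95% HDI (0.44, 0.97), PP 1.00, BF10 36.92
```

The synthetic CHR group couples GSH and SOFAS at Spearman 0.58; with 13
subjects this particular cohort draw happens to correlate more strongly,
and the sampler reports it: the posterior mode of ρ is 0.82, 95% of the
posterior mass lies in (0.44, 0.97), effectively all of it is above zero
(PP 1.00), and the data shift the odds toward a non-zero association by a
factor of ~37. A weaker draw yields a wide HDI straddling zero and a BF₁₀
below 1 — the n = 13 posterior is honest about its uncertainty.

The same cohort run through the GLM (`examples/group_glm.py`) prints the
posterior-summary grid (β0, β_CHR, β_HC, β_sofas, σ_β, σ_i, the group
difference and its effect size), where β_CHR = −β_HC exactly in every
draw.

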