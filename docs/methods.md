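# Methods

`gshcohort` implements the statistical chain of a two-group clinical
magnetic-resonance-spectroscopy study: a cohort of clinical high-risk (CHR)
and healthy-control (HC) participants with a brain glutathione (GSH)
concentration, its Cramér–Rao lower bound (CRLB) from spectral fitting, and
clinical scores (SOFAS functioning 0–100, SOPS symptom total, CAST 6–30,
AUDIT-C 0–12). This note documents the models, the priors, the samplers,
the synthetic-data generator, and the numerical and design choices.

## Quality-control filter

Records enter the analyses only if their GSH CRLB is strictly below 30%
(missing CRLB excludes the record). The filter runs before every statistic
in the pipeline. It is idempotent and monotone in the threshold.

## Bayesian Spearman correlation (latent-normal data augmentation)

The observed ranks of two paired variables are modelled as the degraded
image of latent scores (z_x, z_y) from a standard bivariate normal with
correlation ρ, with prior ρ ~ Uniform[−1, 1]. A Metropolis-within-Gibbs
sampler alternates:

1. **Latent updates.** Each latent score has the conditional
   N(ρ·z_partner, 1−ρ²) truncated to the interval between the largest
   latent value of any observation with strictly lower rank and the
   smallest latent value of any observation with strictly higher rank.
   Tied observations (midranks) constrain only against non-tied
   neighbours. Updates proceed as an even/odd (chromatic) blocked Gibbs
   sweep over tie groups: a tie group only constrains its rank-adjacent
   neighbours, so alternating parities is a valid Gibbs scheme with the
   same stationary distribution as a site-by-site sweep, and each phase is
   one vectorized truncated-normal draw (inverse-CDF; numerically empty
   intervals fall back to the interval midpoint, never an order-violating
   value).
2. **ρ update.** Random-walk Metropolis with a normal step under the
   bivariate-normal likelihood of the latent pairs. The step scale adapts
   toward ~40% acceptance during burn-in (Robbins–Monro-damped) and is
   frozen afterwards; the realized acceptance rate is stored in the chain
   diagnostics.

Latents initialize at the normal quantiles of (rank − 0.5)/n; ρ at the
classical Spearman coefficient clipped to ±0.9. Defaults retain 11,000
draws after thinning by 10 and discarding 1,000 retained-scale burn-in
iterations; the "pre-thinning" counting convention is reachable by
configuring `n_kept=1100, thin=10`. Pairs with a missing member are
dropped listwise before ranking.

**Reporting scale.** Summaries (mode, 95% HDI, PP) and the Bayes factor are
computed directly on the sampled latent correlation, whose prior is the
uniform. The alternative convention — converting draws to the exact rank
scale via (6/π)·asin(ρ/2) — differs by less than 0.02 over |ρ| ≤ 0.6 and
leaves the Savage–Dickey ratio unchanged (it is invariant under smooth
monotone reparameterization), so the simpler scale is reported.

**Bayes factor.** BF₁₀ = prior density at ρ = 0 (0.5 for the uniform)
divided by the posterior density there, estimated from the draws by the
boundary-corrected KDE described below. A `prior_only` mode disables the
likelihood so the chain samples the prior — a calibration check in which
BF₁₀ ≈ 1 by construction.

## Hierarchical group GLMs

Two models share one sampler, with y either a clinical score or GSH:

    y_i = β0 + β_group(i) + ε_i
    y_i = β0 + β_group(i) + β_cov · x_i + ε_i,    ε_i ~ N(0, σ_i²)

Priors are scaled from the data (SD below is the sample SD of y):

| parameter | prior | note |
|---|---|---|
| β0 | N(mean(y), (5·SD)²) | wide, anchored at the data mean |
| β_group | N(0, σ_β²) | shared SD: groups inform each other |
| σ_β | Gamma(shape = SD/2, rate = 2·SD) | shrinkage hyperprior |
| σ_i | Uniform(SD/1000, 1000·SD) | wide data-scaled bounds |
| β_cov | N(0, (2·SD(y)/SD(x))²) | covariate slope; x mean-centered |

The quoted precision-style expressions behind β0 and β_cov — 1/(SD·5)² and
1/(2·SD(y)/SD(x))² — are read as precisions, giving the SDs above; that is
the only reading under which the priors are wide. The covariate is
mean-centered so β0 keeps its data-mean anchoring.

**Sampler.** Conjugate normal Gibbs updates for β0, each deflection, and
β_cov; adaptive random-walk Metropolis on log σ_i (bounded by the uniform
prior) and log σ_β (with the log-transform Jacobian). Each parameter block
draws from its own child seed stream, so adding an inert block (e.g. an
identically-zero covariate) leaves the other blocks' draws bit-identical.
Retained draws are recentred per draw to the sum-to-zero parameterization:
the baseline absorbs the deflection mean and the two deflections are stored
as +d/−d with d computed once, making them exact floating-point negatives.
The between-group difference is the per-draw deflection difference
(β_HC − β_CHR by default) and the effect size divides it by the per-draw
σ_i — the definition under which the reported difference and residual-SD
scales are arithmetically consistent.

**Properties of the literal hyperprior.** Gamma(SD/2, 2·SD) has mean 1/4 on
every data scale. For a large-SD response (e.g. SOFAS, SD ≈ 9.5 → shape
4.75, rate 19) it concentrates near 0.25 and therefore shrinks group
deflections of several score points essentially to zero; the group signal
is absorbed by σ_i. For a small-SD response (GSH, shape ≈ 0.15 < 1) the
density diverges (integrably) at 0, producing genuine spike-and-slab-like
bimodality: part of the posterior sits at σ_β ≈ 0 with null deflections.
Chains mix between the modes (verified across sampler seeds); this is
posterior structure, not a sampler defect. Users comparing groups on a
large-SD score should be aware the model is deliberately conservative
there.

One listed self-check — that with pure-noise data the β0 posterior SD
approaches its prior SD — is not attainable under data-scaled priors: the
likelihood always contributes precision ≈ n/SD², so the β0 posterior SD is
~SD/√n, far below 5·SD, for any usable n. It is documented here instead of
tested.

## Posterior summaries

* **HDI** — the narrowest contiguous window of ⌈mass·n⌉ sorted draws
  (exact for unimodal samples, deterministic given the draws).
* **Mode** — argmax of a Gaussian KDE with Silverman bandwidth on a
  512-point grid. With known support (ρ ∈ [−1,1]; σ > 0) the sample is
  reflected about each finite bound before density evaluation, removing
  boundary bias where mass piles up at an edge; the mode is clipped into
  the support.
* **PP (posterior proportion)** — max of the fractions of draws above and
  below zero; exact zeros count to neither side and an all-zero sample
  returns 0.5. Always in [0.5, 1].
* **Savage–Dickey BF₁₀** — prior/posterior density ratio at the null,
  posterior density from the same boundary-corrected KDE (the latent-rank
  posterior has no closed form, so no parametric shortcut is taken).
* **ESS** — Geyer initial-monotone-sequence estimator, logged per column.

## Frequentist replication suite

Standard tests behind a uniform result type: Pearson chi-squared on 2×2
counts (df 1, **no continuity correction** — the convention that exactly
reproduces the published gender statistic 1.948 from its counts), pooled
two-sample t (Welch by flag), Spearman correlation of midranks,
hierarchical (two-step) OLS with the R²-change F test
F = (ΔR²/k_added)/((1−R²_full)/(n−k_total−1)), one-way ANOVA with Tukey HSD,
and a median split in which values equal to the median go to the *low*
subgroup — the convention forced by the published 7/6 split of 13
patients. Diagnosis is dummy coded CHR = 0, HC = 1.

## Synthetic cohort generator

The generator draws cohorts at the study conditions: group sizes 13/30;
SOFAS 67.7 ± 9.5 (CHR) vs 82.7 ± 3.8 (HC); CAST 11.4 ± 7.8 vs 6.2 ± 0.8 on
[6,30]; AUDIT-C 5.5 ± 3.8 vs 5.9 ± 2.5 on [0,12]; SOPS 8.4 ± 5.0 (CHR
only); CRLB 10 ± 4 / 11 ± 4 % truncated above 1%; GSH residual SD 0.27 mM;
within-group GSH–SOFAS Spearman targets 0.58 (CHR) and 0.11 (HC). GSH and
SOFAS are coupled through a Gaussian copula using the exact conversion
r = 2·sin(πρₛ/6); bounded scores are drawn on the latent normal scale,
clipped and rounded (the HC CAST marginal sits at the scale floor of 6, so
clipping reproduces its floor pile-up qualitatively); GSH is truncated
positive by resampling. GSH group means (CHR 1.74, HC 1.47 mM) are
synthetic choices bracketing the 1.60 mM median-split threshold with a
0.27 mM raw gap — the study never prints the group means.

What the generator does **not** emulate: CRLB–concentration coupling,
spectral-fitting noise, discrete questionnaire item structure, covariance
between scores other than GSH–SOFAS, or missingness patterns. Passing
recovery/calibration tests on these cohorts therefore demonstrates that
the samplers estimate what they claim under the stated dependence
structure — not that the generator reproduces every feature of real MRS
data. Note one interaction worth knowing: because the raw GSH gap and a
positive GSH–SOFAS slope coexist with a large SOFAS group gap, the
SOFAS-adjusted group difference on synthetic cohorts is larger in
magnitude (~−0.5 mM) than the raw gap.

## Pipeline and reproducibility

`run_full_analysis` executes: CRLB filter (<30%); Bayesian Spearman for
(CHR: SOFAS, SOPS, CAST) and (HC: SOFAS); group GLMs for CAST, AUDIT-C,
SOFAS; the GSH model with the SOFAS covariate; the frequentist suite. A
cohort without SOPS values skips that correlation with a logged warning.
Every stage derives its seed from the master seed and the stage name
(CRC32 mix, < 2³¹), so stages re-run identically in isolation and two runs
with one seed render byte-identical JSON. Stage-level logging reports
group sizes, acceptance rates and ESS.

## Problem sizes

Default sampler settings mirror the study (11,000 retained draws, thin 10,
burn-in 1,000). The test suite and the acceptance script run the same code
at 1,000–3,000 retained draws with thin 1–2 and burn-in 200–500, and use
20 seeded replicates for calibration/recovery checks at n = 30–430 — sizes
at which the Monte-Carlo error of the checked summaries is comfortably
inside the asserted tolerances.

## Known limitations

* Single-chain samplers; convergence is monitored by ESS and acceptance
  rates, not cross-chain R-hat.
* The KDE mode/density use a fixed Silverman bandwidth; heavily multimodal
  posteriors (the σ_β spike-and-slab above) are summarized but the single
  "mode" number is then a partial description.
* Only two groups are supported in the GLM (the study design); k-group
  generalization is structural but untested.
* Published posterior tables and Bayes factors from the original cohort
  cannot be reproduced without the raw data; the package verifies the
  machinery by structural identities, closed-form oracles, and
  recovery/calibration on synthetic cohorts instead.
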