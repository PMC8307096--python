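"""Bayesian Spearman correlation between glutathione and functioning.

Runs the latent-normal Metropolis-within-Gibbs sampler on the CHR group of
a synthetic cohort and prints the posterior mode of rho, its 95% highest
density interval, the posterior proportion (PP, the fraction of posterior
mass on the dominant side of zero) and the Savage-Dickey Bayes factor BF10
(>1 favours a non-zero association).
"""

from gshcohort import bayesian_spearman, default_config, filter_by_crlb, generate_cohort

cohort = filter_by_crlb(generate_cohort(default_config(seed=7)))
chr_group = cohort.select("CHR")

res = bayesian_spearman(
    chr_group.values("gsh"), chr_group.values("sofas"),
    n_kept=4000, thin=2, burn_in=500, seed=7,
)
s = res.rho_summary
print(f"CHR GSH ~ SOFAS (n={res.n}):")
print(f"  rho mode {s.mode:.2f}, 95% HDI ({s.hdi_low:.2f}, {s.hdi_high:.2f}), "
      f"PP {s.pp:.2f}, BF10 {res.bf10:.2f}")
print("The generator couples GSH and SOFAS at Spearman 0.58 inside CHR; with only")
print("13 subjects the posterior is wide, so the mode scatters around that target.")
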