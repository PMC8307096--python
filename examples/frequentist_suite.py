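"""Classical replication: demographics tests, hierarchical regression and
the glutathione median split.

Prints a demographics grid (chi-squared for gender, pooled t-tests for the
continuous scores), the R^2-change F test of adding diagnosis (CHR=0, HC=1)
over SOFAS as GSH predictors, and the CHR median split at the sample
median of glutathione.
"""

import numpy as np

from gshcohort import (
    default_config,
    filter_by_crlb,
    generate_cohort,
    hierarchical_regression,
    median_split,
    pearson_chi2,
    two_sample_t,
)

cohort = filter_by_crlb(generate_cohort(default_config(seed=5)))

chr_g, hc_g = cohort.select("CHR"), cohort.select("HC")
counts = [[sum(r.gender == "male" for r in g), sum(r.gender == "female" for r in g)]
          for g in (chr_g, hc_g)]
chi = pearson_chi2(counts)
print(f"gender   chi2={chi.statistic:6.3f}  p={chi.p_value:.3f}   counts={counts}")
for var in ("age", "cast", "audit_c", "sofas"):
    t = two_sample_t(chr_g.values(var), hc_g.values(var))
    print(f"{var:<8} t={t.statistic:8.3f}  p={t.p_value:.3f}   df={t.df:g}")

gsh = cohort.values("gsh")
sofas = cohort.values("sofas")
dummy = np.array([0.0 if r.group == "CHR" else 1.0 for r in cohort.records])
hr = hierarchical_regression(gsh, sofas, dummy, names=["sofas", "group_hc"])
print(f"\nstep 1 (SOFAS):        adj R2={hr.step1_adj_r2:.3f}  F{hr.step1_df}={hr.step1_f:.3f}")
print(f"step 2 (+ diagnosis):  dR2={hr.delta_r2:.3f}  F-change{hr.f_change_df}={hr.f_change:.3f} "
      f"p={hr.f_change_p:.3f}")
B, tv, p = hr.coefficients["group_hc"]
print(f"diagnosis coefficient: B={B:.3f} t={tv:.2f} p={p:.3f} "
      "(negative = HC lower GSH at equal SOFAS)")

labels = median_split(chr_g.values("gsh"))
print(f"\nCHR median split: {np.sum(labels == 'low')} low / {np.sum(labels == 'high')} high "
      f"at {np.median(chr_g.values('gsh')):.2f} mM")
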