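"""Null behaviour of the combined statistic.

Under the global null (neither trait associated with the variant) the two
effect estimates are independent — even with correlated traits and
overlapping cohorts, because the adjusted fit conditions on the covariate
trait — so the combined statistic is chi-square with 2 df. This script
checks that empirically on the nested 5,000/3,000 design.
"""

from btob import ScenarioConfig, null_diagnostics

config = ScenarioConfig(h2_1=0.0, h2_2=0.0, rho=0.8, n1=5000, n2=3000,
                        n_overlap=3000, reps=1000, seed=7)
d = null_diagnostics(config)

print(f"KS distance vs chi2(2):        {d.ks_stat:.4f}  (p = {d.ks_pvalue:.3f})")
print(f"corr(beta1_hat, beta2*_hat):   {d.beta_correlation:+.4f}")
print(f"GC lambda of the replicates:   {d.lambda_gc:.4f}")
print("\nA KS p above 0.01, a correlation near zero and lambda near 1 all say")
print("the 2-df reference distribution is the right one despite rho = 0.8 and")
print("a 3,000-person cohort overlap.")
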