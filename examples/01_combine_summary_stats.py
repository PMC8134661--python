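"""Combine a marginal BMI scan with a WHR-adjusted-for-BMI scan per SNP.

Uses the bundled eight-locus example: for each SNP the two z-scores are
squared, summed, and referred to chi-square with 2 df. A combined p-value
below 5e-8 is genome-wide significant for the bivariate trait pair even
though (see example 04) no locus reaches univariate significance.
"""

from btob import gc_lambda, merge_studies, results_to_frame, run_btob
from btob.datasets import example_study_pair

study_bmi, study_whr_adj = example_study_pair()
merged = merge_studies(study_bmi, study_whr_adj, min_n=30_000)
results = run_btob(merged)

table = results_to_frame(results)
print(table[["snp_id", "chrom", "z1", "z2", "chi2", "p_btob"]].to_string(index=False))
print(f"\nGC lambda (df=2) over these statistics: {gc_lambda(table['chi2'], df=2):.3f}")
print("chi2 = z1^2 + z2^2; p_btob = exp(-chi2/2); values below 5e-8 are genome-wide significant.")
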