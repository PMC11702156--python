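"""Family-wise error rate of the extended-AIC scan under a global null.

Draws outcomes independent of 100 regressors and scans the null model
against every single-variable model; the fraction of replicates where a
non-null model wins estimates the FWER, which the theory pins near the
scan level alpha. The analytic finite-p value 1 - F(x_{p,alpha})**p is
printed for comparison.
"""

from eaic import SimSetting, asymptotic_fwer, critical_bound, run_null_study

alpha, p, reps = 0.05, 100, 300

analytic = asymptotic_fwer(p, critical_bound(p, alpha).x)
print(f"scan level alpha = {alpha}, p = {p} candidate regressors")
print(f"analytic asymptotic FWER: {analytic:.4f}\n")

for family in ("linear", "logistic"):
    setting = SimSetting(family, n=100, p=p, rho=0.0, reps=reps, seed=42)
    metrics = run_null_study(setting, alpha=alpha)
    print(f"{family:<9} n=100: estimated FWER = {metrics.fwer:.3f} "
          f"(+/- {metrics.fwer_se:.3f} SE, {reps} replicates)")

print(
    "\nReading: the scan wrongly rejects the global null about 5% of the\n"
    "time, as designed. The linear estimate sits within Monte-Carlo error of\n"
    "the analytic value; the logistic one can run slightly above it at n=100,\n"
    "where the chi-square approximation of the test statistics is rougher."
)
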