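"""Reduced-scale comparison of seven selectors on the full procedure.

One setting (linear, n=1000, p=100, uncorrelated, SNR=1, 10 active
variables), 50 replicates: each replicate simulates data, runs the LASSO
path, refits without penalty, and lets each criterion (plus the oracle,
which knows the active count) pick a model.
"""

from eaic import SimSetting, run_full_study

setting = SimSetting(
    "linear", n=1000, p=100, rho=0.0, snr=1.0, n_active=10, reps=50, seed=123
)
print(f"setting: {setting}\n")
print(f"{'method':<18} {'FWER':>6} {'FDR':>6} {'mean TP':>8} {'sens.':>6}")
for m in run_full_study(setting):
    print(f"{m.method:<18} {m.fwer:6.2f} {m.fdr:6.3f} {m.mean_tp:8.1f} {m.sensitivity:6.2f}")

print(
    "\nReading: FWER is the share of replicates with at least one inactive\n"
    "variable selected; mean TP counts recovered active variables (of 10).\n"
    "The AIC selects false positives almost every time, while the criteria\n"
    "that penalize for the number of candidates (mAIC, mBIC, EBIC and the\n"
    "extended AIC at alpha=0.05) keep the FWER near the nominal level at a\n"
    "small cost in sensitivity."
)
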