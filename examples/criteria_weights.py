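"""Penalty weights and coincidence levels of the extended AIC.

Every information criterion here scores a support A as -2 l(A) + w |A|
(EBIC aside). The extended AIC's weight 2 x_{p, alpha} is chosen so the
implicit multiple likelihood-ratio testing over p candidate regressors has
asymptotic family-wise error rate alpha; specific alphas make it collapse
onto the classical criteria.
"""

from eaic import ALPHA0, CriterionSpec, alpha_bic_equiv, alpha_maic, alpha_ric

n, p = 452914, 1692  # a spontaneous-reporting pharmacovigilance scale

print(f"Per-variable penalty weights at n={n}, p={p}:")
for name, constants in [
    ("AIC", {}), ("BIC", {}), ("RIC", {}), ("mAIC", {"c": 0.5}),
    ("mBIC", {"E": 4.0}), ("EAIC", {"alpha": 0.05}), ("EAIC", {"alpha": 0.5}),
]:
    spec = CriterionSpec(name, n, p, constants)
    print(f"  {spec.label:<18} w = {spec.weight():8.4f}")

print()
print(f"alpha0 (simplest-form FWER level)        = {ALPHA0:.5f}")
print(f"alpha_RIC(p={p})  (EAIC == RIC)        = {alpha_ric(p):.4f}")
print(f"alpha_mAIC(p={p}, c=1/2) (EAIC == mAIC) = {alpha_maic(p, 0.5):.4f}")
print(f"EAIC == BIC equivalence level            = {alpha_bic_equiv(n, p):.4f}")
print()
print(
    "Reading: selecting with the EAIC at the last level is mathematically\n"
    "identical to selecting with the BIC at this (n, p); at smaller alpha the\n"
    "EAIC penalizes each extra variable more than the BIC does."
)
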