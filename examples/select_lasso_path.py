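"""Full selection procedure on one synthetic dataset.

Simulates a linear model with 10 active variables out of 100, runs the
LASSO path, refits every support without penalty, and compares the models
that the AIC, BIC and extended AIC pick.
"""

import numpy as np

from eaic import (
    CriterionSpec,
    Dataset,
    SimSetting,
    lasso_path_supports,
    select_by_criterion,
)
from eaic.simulate import calibrate_coeffs, draw_coefficients, draw_design, draw_outcome

rng = np.random.default_rng(7)
n, p, snr = 1000, 100, 1.0
columns = tuple(f"X{j + 1}" for j in range(p))

X = draw_design(n, p, rho=0.0, rng=rng)
raw = draw_coefficients(columns, n_active=10, rng=rng)
draw = calibrate_coeffs(X, columns, raw, target_snr=snr, family="linear")
beta = np.zeros(p)
for name, b in draw.beta.items():
    beta[columns.index(name)] = b
y = draw_outcome(X, beta, draw.intercept, "linear", rng)
data = Dataset(X=X, y=y, family="linear", columns=columns)
active = frozenset(draw.active_ids)

path = lasso_path_supports(data, dfmax=100)
print(f"LASSO path: {len(path.supports)} distinct supports, sizes {path.sizes()[:8]}...")
print(f"True active set ({len(active)}): {sorted(active)}\n")

for name, constants in [("AIC", {}), ("BIC", {}), ("EAIC", {"alpha": 0.05})]:
    spec = CriterionSpec(name, n=n, p=p, constants=constants)
    sel = select_by_criterion(path, data, spec)
    chosen = sel.chosen.support
    fp = sorted(chosen - active)
    missed = sorted(active - chosen)
    print(f"{spec.label:<18} selected {len(chosen):2d} variables | "
          f"false positives: {fp or 'none'} | missed: {missed or 'none'}")

print(
    "\nReading: the AIC's weight (2) is far below the multiplicity-corrected\n"
    "threshold, so it drags spurious variables in; the extended AIC at\n"
    "alpha=0.05 keeps the false-positive probability near 5%."
)
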