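"""Probit concentration-mortality analysis with LC confidence limits.

Simulates a 7-dose bioassay (30 insects per dose, 48-h mortality) from a
known dose-response line, fits the binomial-probit model and prints the
LC10/LC30/LC50 table, then shows the internal-consistency check that two
LC anchors pin down every other LC value.
"""

import numpy as np
from scipy.stats import norm

from arenawalk.doseresp import fit_probit, probit_line_through

rng = np.random.default_rng(5)
doses = np.array([10000.0, 5000.0, 2500.0, 1250.0, 625.0, 312.5, 156.25])
a_true, b_true = -6.0, 1.9
dead = rng.binomial(30, norm.cdf(a_true + b_true * np.log10(doses)))

fit = fit_probit(dose=doses, n=np.full(7, 30), dead=dead)
print(f"intercept {fit.intercept:.3f}, slope {fit.slope:.3f} "
      f"(true {a_true}, {b_true})")
print(f"goodness of fit: chi2 = {fit.chi2:.2f} on {fit.df} df")
print(fit.lc_table([0.1, 0.3, 0.5]).round(1).to_string(index=False))
# Each row is the concentration (ppm) killing that fraction in 48 h,
# with 95% delta-method confidence limits.

line = probit_line_through(395.0, 0.10, 1992.0, 0.50)
print(f"\nLC30 implied by LC10=395 and LC50=1992: {line.lc(0.3).lc:.0f} ppm")
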