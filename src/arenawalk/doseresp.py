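"""Probit concentration-mortality analysis.

The classical bioassay dose-response model: the probability that an
individual dies at dose d follows Phi(a + b * log10 d). The fit is a
binomial GLM with probit link (exact likelihood, so 0% and 100% kill
groups need no empirical-probit correction), with an optional Abbott
correction for control mortality. Lethal concentrations LC_p and their
confidence limits come from the fitted line by the delta method on the
log10 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import InvalidParameterError, NonEstimableError

__all__ = ["ProbitFit", "LCEstimate", "fit_probit", "lc", "probit_line_through"]


@dataclass
class LCEstimate:
    p: float
    lc: float
    lower: float
    upper: float


@dataclass
class ProbitFit:
    """Fitted line probit(p) = intercept + slope * log10(dose)."""

    intercept: float
    slope: float
    cov: np.ndarray           # 2x2 covariance of (intercept, slope)
    chi2: float               # Pearson goodness-of-fit
    df: int                   # n_doses - 2
    n_doses: int
    control_mortality: float = 0.0

    def lc(self, p: float, alpha: float = 0.05) -> LCEstimate:
        return lc(self, p, alpha=alpha)

    def lc_table(self, ps: Sequence[float] = (0.1, 0.3, 0.5)) -> pd.DataFrame:
        rows = [self.lc(p) for p in ps]
        return pd.DataFrame([{"p": r.p, "lc": r.lc, "lower": r.lower,
                              "upper": r.upper} for r in rows])

    def to_json(self, path, ps: Sequence[float] = (0.1, 0.3, 0.5)) -> None:
        out = {
            "intercept": self.intercept, "slope": self.slope,
            "cov": np.asarray(self.cov).tolist(),
            "chi2": self.chi2, "df": self.df,
            "control_mortality": self.control_mortality,
            "lc": [vars(self.lc(p)) for p in ps],
        }
        from pathlib import Path
        Path(path).write_text(json.dumps(out, indent=2))


def _as_arrays(data, dose, n, dead):
    if data is not None:
        df = pd.DataFrame(data)
        dose, n, dead = (df["dose"].to_numpy(float), df["n"].to_numpy(float),
                         df["dead"].to_numpy(float))
    else:
        dose = np.asarray(dose, dtype=float)
        n = np.asarray(n, dtype=float)
        dead = np.asarray(dead, dtype=float)
    if (dose <= 0).any():
        raise InvalidParameterError("doses must be > 0")
    if ((dead < 0) | (dead > n)).any() or (n <= 0).any():
        raise InvalidParameterError("need 0 <= dead <= n and n > 0")
    return dose, n, dead


def fit_probit(data=None, *, dose=None, n=None, dead=None,
               control_mortality: float = 0.0) -> ProbitFit:
    """Maximum-likelihood binomial-probit fit on log10 dose.

    Parameters
    ----------
    data:
        Anything DataFrame-like with columns ``dose`` (ppm), ``n``
        exposed and ``dead``; alternatively pass the three arrays.
    control_mortality:
        Natural-response proportion c; when positive, observed kill
        proportions are Abbott-corrected to (p - c) / (1 - c) before
        fitting.

    Raises
    ------
    NonEstimableError
        With fewer than two distinct doses, or complete separation
        (everything dead or everything alive overall).
    """
    dose_a, n_a, dead_a = _as_arrays(data, dose, n, dead)
    if len(np.unique(dose_a)) < 2:
        raise NonEstimableError("need >= 2 distinct doses")
    if not 0 <= control_mortality < 1:
        raise InvalidParameterError("control_mortality must be in [0, 1)")
    prop = dead_a / n_a
    if control_mortality > 0:
        prop = np.clip((prop - control_mortality) / (1.0 - control_mortality), 0.0, 1.0)
    total = float((prop * n_a).sum())
    if total <= 0 or total >= n_a.sum():
        raise NonEstimableError("all-alive or all-dead data: probit line not estimable")
    exog = sm.add_constant(np.log10(dose_a))
    model = sm.GLM(prop, exog, family=sm.families.Binomial(sm.families.links.Probit()),
                   var_weights=n_a)
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels internal failures
        raise NonEstimableError(f"probit fit failed: {exc}") from exc
    a, b = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params())
    mu = np.clip(res.mu, 1e-12, 1 - 1e-12)
    chi2 = float(np.sum(n_a * (prop - mu) ** 2 / (mu * (1 - mu))))
    return ProbitFit(intercept=a, slope=b, cov=cov, chi2=chi2,
                     df=max(len(dose_a) - 2, 0), n_doses=len(dose_a),
                     control_mortality=control_mortality)


def lc(fit: ProbitFit, p: float, alpha: float = 0.05) -> LCEstimate:
    """Lethal concentration LC_p with delta-method confidence limits.

    LC_p = 10 ** ((probit(p) - a) / b); the variance of log10 LC_p uses
    the gradient (-1/b, -(probit(p) - a)/b^2) against the parameter
    covariance, and the limits are exponentiated back to ppm.
    """
    if not 0 < p < 1:
        raise InvalidParameterError("p must be in (0, 1)")
    if fit.slope <= 0:
        raise InvalidParameterError("slope must be > 0 for a monotone dose response")
    g = float(norm.ppf(p))
    log_lc = (g - fit.intercept) / fit.slope
    grad = np.array([-1.0 / fit.slope, -(g - fit.intercept) / fit.slope ** 2])
    var = float(grad @ np.asarray(fit.cov) @ grad)
    var = max(var, 0.0)
    z = float(norm.ppf(1.0 - alpha / 2.0))
    half = z * np.sqrt(var)
    return LCEstimate(p=p, lc=float(10.0 ** log_lc),
                      lower=float(10.0 ** (log_lc - half)),
                      upper=float(10.0 ** (log_lc + half)))


def probit_line_through(lc1: float, p1: float, lc2: float, p2: float) -> ProbitFit:
    """The unique probit line passing exactly through two (LC_p, p) anchors.

    Useful for internal-consistency checks: two quoted lethal
    concentrations pin down intercept and slope, and every other LC_p
    follows. Covariance is zero (the line is exact, not estimated).
    """
    for p in (p1, p2):
        if not 0 < p < 1:
            raise InvalidParameterError("p must be in (0, 1)")
    if lc1 <= 0 or lc2 <= 0 or lc1 == lc2 or p1 == p2:
        raise InvalidParameterError("anchors must be distinct with positive doses")
    g1, g2 = norm.ppf(p1), norm.ppf(p2)
    x1, x2 = np.log10(lc1), np.log10(lc2)
    b = float((g2 - g1) / (x2 - x1))
    a = float(g1 - b * x1)
    if b <= 0:
        raise InvalidParameterError("anchors imply a non-increasing dose response")
    return ProbitFit(intercept=a, slope=b, cov=np.zeros((2, 2)), chi2=0.0,
                     df=0, n_doses=2)
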