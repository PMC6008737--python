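"""Derivation of APM weighting rules from cohort data.

Two derivations are supported, mirroring how a nutritional predictor can be
folded into an additive severity score:

* **Linear anchor rule** — a multivariable logistic fit of death on APM
  thickness (mm) controlling for the physiologic variables; when the APM
  coefficient is close (default 25% relative, after sign alignment) to the
  per-point Glasgow Coma Scale coefficient, APM is scored GCS-style as
  ``max(0, anchor - t)`` with the anchor at the cohort median thickness.
* **Categorical weights** — the death-probability curve over thickness is
  estimated by univariate logistic regression; cutpoints are chosen at the
  cohort median and at the point of steepest decline below it; category odds
  ratios versus the reference (thickest) group, rounded to integers, become
  the weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .severity import ValidationError, WeightRule, round_half_away

__all__ = [
    "LogisticFit",
    "RiskCurve",
    "CoefficientComparison",
    "SeparationError",
    "fit_logistic",
    "compare_coefficients",
    "derive_linear_rule",
    "estimate_risk_curve",
    "select_breakpoints",
    "derive_category_weights",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit with Wald inference."""

    params: pd.Series          # coefficients B (including "intercept")
    bse: pd.Series             # standard errors
    pvalues: pd.Series
    llf: float
    converged: bool
    nobs: int
    ci_level: float = 0.95

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("intercept"))

    def conf_int(self) -> pd.DataFrame:
        """Wald CI on the OR scale: exp(B +/- z * SE)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + self.ci_level / 2)
        b = self.params.drop("intercept")
        se = self.bse.drop("intercept")
        return pd.DataFrame(
            {"or": np.exp(b), "low": np.exp(b - z * se), "high": np.exp(b + z * se)}
        )

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "B": self.params.drop("intercept"),
                "SE": self.bse.drop("intercept"),
                "OR": ci["or"],
                "ci_low": ci["low"],
                "ci_high": ci["high"],
                "p": self.pvalues.drop("intercept"),
            }
        )


def fit_logistic(outcome, predictors: pd.DataFrame, ci_level: float = 0.95,
                 maxiter: int = 100) -> LogisticFit:
    """Fit death ~ predictors by maximum likelihood (Newton scoring).

    Raises :class:`SeparationError` naming the offending predictor under
    complete or quasi-complete separation, and ``ValidationError`` when the
    outcome is single-class or a predictor is constant.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError("outcome must contain both classes coded 0/1")
    for name in X.columns:
        if X[name].nunique() <= 1:
            raise ValidationError(f"predictor '{name}' is constant")
    Xc = sm.add_constant(X, prepend=True).rename(columns={"const": "intercept"})
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=FutureWarning)
        try:
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=maxiter,
                                      tol=1e-10, disp=0, warn_convergence=False)
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise SeparationError(
                f"logistic fit failed (likely separation): {exc}"
            ) from exc
    params = pd.Series(res.params, index=Xc.columns)
    bse = pd.Series(res.bse, index=Xc.columns)
    # quasi-separation shows up as runaway coefficients / exploding SEs
    for name in X.columns:
        if abs(params[name]) > 25 or bse[name] > 1e3:
            raise SeparationError(
                f"separation detected on predictor '{name}' "
                f"(B={params[name]:.3g}, SE={bse[name]:.3g})"
            )
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            f"logistic fit did not converge in {maxiter} iterations "
            f"(final params {params.to_dict()})"
        )
    return LogisticFit(
        params=params,
        bse=bse,
        pvalues=pd.Series(res.pvalues, index=Xc.columns),
        llf=float(res.llf),
        converged=True,
        nobs=int(res.nobs),
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class CoefficientComparison:
    """Outcome of the APM-vs-GCS coefficient closeness check."""

    var_a: str
    var_b: str
    b_a: float
    b_b: float
    rel_tol: float
    close: bool

    @property
    def ratio(self) -> float:
        return abs(self.b_a) / abs(self.b_b) if self.b_b != 0 else math.inf


def compare_coefficients(fit: LogisticFit, var_a: str, var_b: str,
                         rel_tol: float = 0.25) -> CoefficientComparison:
    """Decide whether two per-unit coefficients are close.

    Signs are aligned first (both taken per unit toward higher risk), so a
    protective ``-0.45`` per mm and a harmful ``+0.40`` per point lost
    compare as 0.45 vs 0.40.
    """
    for v in (var_a, var_b):
        if v not in fit.params.index:
            raise ValidationError(f"predictor '{v}' not present in fit")
    a, b = abs(float(fit.params[var_a])), abs(float(fit.params[var_b]))
    close = abs(a - b) <= rel_tol * max(a, b)
    return CoefficientComparison(var_a, var_b, float(fit.params[var_a]),
                                 float(fit.params[var_b]), rel_tol, close)


def derive_linear_rule(decision: CoefficientComparison,
                       anchor: int = 15) -> tuple[WeightRule | None, dict]:
    """Emit the GCS-style linear anchor rule when the closeness check passed.

    When the coefficients are not close, no rule is emitted and the
    diagnostic carries the coefficient ratio instead.
    """
    info = {
        "close": decision.close,
        "b_apm": decision.b_a,
        "b_gcs": decision.b_b,
        "ratio": decision.ratio,
        "rel_tol": decision.rel_tol,
        "anchor": anchor,
    }
    if not decision.close:
        return None, info
    rule = WeightRule(kind="linear_anchor", anchor=anchor, provenance="fitted")
    return rule, info


@dataclass
class RiskCurve:
    """Estimated death probability over an integer-mm thickness grid."""

    grid: np.ndarray               # strictly increasing thickness values (mm)
    prob: np.ndarray               # estimated P(death | t) on the grid
    method: str                    # "logistic" | "empirical"
    empirical: pd.DataFrame        # per-mm death rate with counts
    intercept: float = math.nan
    slope: float = math.nan        # per-mm log-odds (logistic method)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("risk-curve grid must be strictly increasing")
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValidationError("risk-curve probabilities outside [0, 1]")

    def slope_at(self, t: float) -> float:
        """dP/dt of the fitted logistic curve at thickness ``t``."""
        if self.method != "logistic":
            raise ValidationError("slope only defined for the logistic method")
        p = 1.0 / (1.0 + math.exp(-(self.intercept + self.slope * t)))
        return self.slope * p * (1 - p)


def _empirical_rates(t: np.ndarray, y: np.ndarray, grid: np.ndarray) -> pd.DataFrame:
    rows = []
    ti = np.round(t).astype(int)
    for g in grid:
        mask = ti == g
        n = int(mask.sum())
        rows.append({"t": int(g), "n": n,
                     "deaths": int(y[mask].sum()),
                     "rate": float(y[mask].mean()) if n else math.nan})
    return pd.DataFrame(rows)


def estimate_risk_curve(cohort: pd.DataFrame, apm_col: str = "apm_mm",
                        death_col: str = "death") -> RiskCurve:
    """Univariate logistic death-vs-thickness curve on an integer-mm grid.

    Falls back to the empirical per-mm rates (with a warning) when the
    logistic fit separates.
    """
    t = np.asarray(cohort[apm_col], dtype=float)
    y = np.asarray(cohort[death_col], dtype=float)
    if len(t) < 20:
        raise ValidationError("risk curve requires at least 20 patients")
    if len(np.unique(y)) < 2:
        raise ValidationError("risk curve requires both outcomes present")
    grid = np.arange(int(np.floor(t.min())), int(np.ceil(t.max())) + 1)
    emp = _empirical_rates(t, y, grid)
    try:
        fit = fit_logistic(y, pd.DataFrame({apm_col: t}))
    except SeparationError as exc:
        warnings.warn(f"risk-curve logistic fit separated ({exc}); "
                      "falling back to empirical rates", stacklevel=2)
        rates = emp["rate"].ffill().bfill().to_numpy()
        return RiskCurve(grid=grid.astype(float), prob=rates,
                         method="empirical", empirical=emp)
    a = fit.intercept
    b = float(fit.params[apm_col])
    prob = 1.0 / (1.0 + np.exp(-(a + b * grid)))
    return RiskCurve(grid=grid.astype(float), prob=prob, method="logistic",
                     empirical=emp, intercept=a, slope=b)


def select_breakpoints(curve: RiskCurve, cohort_median: float,
                       override: tuple[float, float] | None = None,
                       ) -> tuple[tuple[float, float], str]:
    """Choose the two category cutpoints from the risk curve.

    Default deterministic rule: the upper cutpoint is the cohort median
    thickness; the lower cutpoint is the grid point with maximal absolute
    slope of the fitted curve strictly below the median.  Returns
    ``((lower, upper), provenance)``.
    """
    if override is not None:
        lo, hi = override
        if lo >= hi:
            raise ValidationError("override cutpoints must be strictly increasing")
        return (float(lo), float(hi)), "manual"
    if curve.method != "logistic" or abs(curve.slope) < 1e-12 \
            or float(np.ptp(curve.prob)) < 1e-6:
        raise ValidationError(
            "degenerate (constant) risk curve: supply fixed cutpoints instead"
        )
    if not (curve.grid.min() <= cohort_median <= curve.grid.max()):
        raise ValidationError("cohort median outside the risk-curve grid")
    below = curve.grid[curve.grid < cohort_median]
    if len(below) == 0:
        raise ValidationError("no grid points below the cohort median")
    slopes = np.array([abs(curve.slope_at(g)) for g in below])
    lower = float(below[int(np.argmax(slopes))])
    return (lower, float(cohort_median)), "fitted"


def derive_category_weights(fit: LogisticFit, high: str = "apm_high",
                            mid: str = "apm_mid",
                            cutpoints: tuple[float, float] = (10.0, 15.0),
                            rounding: str = "half_away") -> WeightRule:
    """Integer category weights from ORs vs the reference (thickest) group.

    ``rounding``: ``"half_away"`` (default) or ``"truncate"``.  The weights
    must be non-increasing from HIGH to REF and every non-reference OR must
    exceed 1 (a protective category cannot take positive weight).
    """
    for v in (high, mid):
        if v not in fit.params.index:
            raise ValidationError(f"category indicator '{v}' not present in fit")
    or_high = math.exp(float(fit.params[high]))
    or_mid = math.exp(float(fit.params[mid]))
    for name, orv in (("HIGH", or_high), ("MID", or_mid)):
        if orv < 1.0:
            raise ValidationError(
                f"category {name} has OR {orv:.3f} < 1: protective category "
                "cannot take positive weight"
            )
    if rounding == "half_away":
        w_high, w_mid = round_half_away(or_high), round_half_away(or_mid)
    elif rounding == "truncate":
        w_high, w_mid = int(or_high), int(or_mid)
    else:
        raise ValidationError(f"unknown rounding mode {rounding!r}")
    if not (w_high >= w_mid >= 0):
        raise ValidationError(
            f"non-monotone category weights ({w_high}, {w_mid}, 0): "
            "risk must not increase with thickness"
        )
    return WeightRule(kind="categorical", cutpoints=cutpoints,
                      weights=(w_high, w_mid, 0), provenance="fitted")
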