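"""ROC/AUC machinery with DeLong inference and cohort summary tables.

The AUC is the Mann-Whitney statistic with midrank tie handling,
``P(score_dead > score_alive) + 0.5 * P(tie)``; its variance and the paired
comparison of two correlated AUCs use DeLong's structural components.
Orientation defaults to *raw* — an inversely oriented predictor (thicker
muscle, lower mortality) is reported with AUC < 0.5 rather than silently
flipped; ``orientation="auto"`` flips and records the flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .severity import ValidationError

__all__ = [
    "RocResult",
    "ModelComparison",
    "auc",
    "delong_compare",
    "or_per_point_table",
    "cohort_summary",
]


@dataclass
class RocResult:
    """ROC curve, AUC and DeLong variance for one score."""

    name: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    variance: float      # DeLong variance of the AUC
    ci_level: float
    flipped: bool        # True when orientation="auto" negated the score

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValidationError("ROC points must be monotone non-decreasing")
        if self.variance < 0:
            raise ValidationError("DeLong variance must be non-negative")

    @property
    def ci(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        half = z * math.sqrt(self.variance)
        return (max(0.0, self.auc - half), min(1.0, self.auc + half))

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})

    def plot(self, ax=None):
        """Plot the ROC curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, label=f"{self.name} (AUC={self.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax


@dataclass(frozen=True)
class ModelComparison:
    """Paired DeLong comparison of two correlated AUCs."""

    name_a: str
    name_b: str
    auc_a: float
    auc_b: float
    delta: float
    z: float
    pvalue: float


def _check_labels(labels: np.ndarray) -> None:
    classes = set(np.unique(labels))
    if not classes <= {0, 1} or len(classes) < 2:
        raise ValidationError("labels must contain both classes coded 0/1")


def _midrank_components(scores: np.ndarray, labels: np.ndarray
                        ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components V10 (per death), V01 (per survivor)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)            # midranks on the pooled sample
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    a = float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (r_all[:m] - r_pos) / n           # P(pos_i > random neg) with ties 1/2
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return a, v10, v01


def auc(scores, labels, name: str = "score", orientation: str = "raw",
        ci_level: float = 0.95) -> RocResult:
    """AUC with midrank tie handling, DeLong variance and a Wald CI.

    ``orientation="raw"`` keeps the score as given (AUC < 0.5 allowed for
    inversely oriented predictors); ``"auto"`` negates the score when the raw
    AUC falls below 0.5 and flags the flip.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(s) != len(y):
        raise ValidationError("scores and labels differ in length")
    _check_labels(y)
    if orientation not in ("raw", "auto"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    a, v10, v01 = _midrank_components(s, y)
    flipped = False
    if orientation == "auto" and a < 0.5:
        s = -s
        a, v10, v01 = _midrank_components(s, y)
        flipped = True
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(name=name, fpr=fpr, tpr=tpr, thresholds=thr, auc=a,
                     variance=float(var), ci_level=ci_level, flipped=flipped)


def delong_compare(a_scores, b_scores, labels, name_a: str = "a",
                   name_b: str = "b") -> ModelComparison:
    """Paired DeLong test for the AUC difference of two scores on one cohort."""
    sa = np.asarray(a_scores, dtype=float)
    sb = np.asarray(b_scores, dtype=float)
    y = np.asarray(labels)
    if len(sa) != len(sb) or len(sa) != len(y):
        raise ValidationError("both scores and labels must have equal length")
    _check_labels(y)
    auc_a, va10, va01 = _midrank_components(sa, y)
    auc_b, vb10, vb01 = _midrank_components(sb, y)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    delta = auc_a - auc_b
    if var_delta <= 1e-16:
        z = 0.0 if abs(delta) < 1e-12 else math.copysign(math.inf, delta)
    else:
        z = delta / math.sqrt(var_delta)
    p = 1.0 if z == 0.0 else float(2 * stats.norm.sf(abs(z)))
    return ModelComparison(name_a=name_a, name_b=name_b, auc_a=auc_a,
                           auc_b=auc_b, delta=delta, z=z, pvalue=min(p, 1.0))


def or_per_point_table(cohort: pd.DataFrame, score_names: list[str],
                       death_col: str = "death",
                       ci_level: float = 0.95) -> pd.DataFrame:
    """Univariate per-point OR (with CI and p) and raw-orientation AUC per score."""
    from .derive import fit_logistic

    y = cohort[death_col].to_numpy()
    rows = []
    for name in score_names:
        if name not in cohort.columns:
            raise ValidationError(f"score column '{name}' not in cohort")
        fit = fit_logistic(y, cohort[[name]], ci_level=ci_level)
        ci = fit.conf_int().loc[name]
        roc = auc(cohort[name], y, name=name, ci_level=ci_level)
        lo, hi = roc.ci
        rows.append({
            "score": name,
            "or_per_point": float(ci["or"]),
            "or_ci_low": float(ci["low"]),
            "or_ci_high": float(ci["high"]),
            "p": round(float(fit.pvalues[name]), 4),
            "auc": roc.auc,
            "auc_ci_low": lo,
            "auc_ci_high": hi,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort summary tables
# ---------------------------------------------------------------------------

#: Variables summarised as mean +/- SD and compared by t-test/ANOVA; all other
#: continuous variables use median (Q1-Q3) with rank-based tests.
DEFAULT_NORMAL_VARS = ("age", "albumin_g_dl")

DEFAULT_CATEGORICAL = ("sex", "subtype")

DEFAULT_CONTINUOUS = ("age", "albumin_g_dl", "apm_mm", "apache2", "apache3")


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _fmt_median_iqr(x: pd.Series) -> str:
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:g} ({q1:g}–{q3:g})"


def cohort_summary(cohort: pd.DataFrame, grouping: str = "survivor-status",
                   continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
                   categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
                   normal_vars: tuple[str, ...] = DEFAULT_NORMAL_VARS,
                   ) -> pd.DataFrame:
    """Grouped descriptive table with the field's conventional tests.

    ``grouping``: ``"survivor-status"`` (two groups, t-test / Mann-Whitney /
    chi-square) or ``"apm-category"`` (three thickness groups, ANOVA /
    Kruskal-Wallis / chi-square).  Footnote tags name the test used.
    """
    from .severity import apm_category

    if grouping == "survivor-status":
        keys = cohort["death"].map({0: "survivors", 1: "nonsurvivors"})
        order = ["survivors", "nonsurvivors"]
    elif grouping == "apm-category":
        keys = cohort["apm_mm"].map(lambda t: apm_category(t).value)
        order = ["high", "mid", "ref"]
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    groups = {k: cohort[keys == k] for k in order}
    for k, g in groups.items():
        if len(g) == 0:
            raise ValidationError(f"empty group '{k}'")
        if len(g) == 1:
            raise ValidationError(f"single-patient group '{k}'")
    rows = []
    for var in continuous:
        if var not in cohort.columns:
            continue
        samples = [g[var].dropna() for g in groups.values()]
        if var in normal_vars:
            if len(samples) == 2:
                stat, p = stats.ttest_ind(*samples)
                test = "t-test"
            else:
                stat, p = stats.f_oneway(*samples)
                test = "ANOVA"
            cells = {k: _fmt_mean_sd(g[var]) for k, g in groups.items()}
        else:
            if len(samples) == 2:
                stat, p = stats.mannwhitneyu(*samples, alternative="two-sided")
                test = "Mann-Whitney"
            else:
                stat, p = stats.kruskal(*samples)
                test = "Kruskal-Wallis"
            cells = {k: _fmt_median_iqr(g[var]) for k, g in groups.items()}
        rows.append({"variable": var, **cells, "test": test, "p": round(float(p), 4)})
    for var in categorical:
        if var not in cohort.columns:
            continue
        tab = pd.crosstab(cohort[var], keys)
        tab = tab[[c for c in order if c in tab.columns]]
        _, p, _, _ = stats.chi2_contingency(tab)
        total = len(cohort)
        for level in tab.index:
            cells = {
                k: f"{tab.loc[level, k]} ({100 * tab.loc[level, k] / total:.1f}%)"
                for k in tab.columns
            }
            rows.append({"variable": f"{var}={level}", **cells,
                         "test": "chi-square", "p": round(float(p), 4)})
    counts = {k: len(g) for k, g in groups.items()}
    rows.insert(0, {"variable": "n", **{k: str(v) for k, v in counts.items()},
                    "test": "", "p": math.nan})
    return pd.DataFrame(rows)
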