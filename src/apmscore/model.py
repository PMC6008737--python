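"""Model/Results facade tying scoring, weight derivation and evaluation together.

``ApmApacheModel`` is built from a patient-level cohort (one row per patient
with APM thickness, APACHE II/III totals, GCS and vital status).  ``fit()``
runs the full derivation — the multivariable APM-vs-GCS coefficient check,
the linear anchor rule, the thickness risk curve with breakpoint selection,
and the categorical odds-ratio weights — then builds both composite scores
and evaluates all five scores by univariate logistic regression and
ROC/AUC with paired DeLong comparisons.  The returned ``ApmApacheResults``
carries the fitted rules, the Table-2-style evaluation frame and a
``summary()`` in the style of a statsmodels results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import derive, evaluate, severity
from .severity import PAPER_DEFAULT_WEIGHTS, ValidationError, WeightRule

__all__ = ["ApmApacheModel", "ApmApacheResults"]


class ApmApacheModel:
    """Composite APACHE-APM scoring model for one cohort.

    Parameters
    ----------
    data : DataFrame with at least ``apm_mm``, ``apache2``, ``apache3``,
        ``gcs`` and ``death`` columns (the cohort CSV schema).
    control_cols : columns used as physiologic controls in the multivariable
        APM fit; by default the per-variable point columns ``phys_pts_*``
        (plus GCS points) when present, otherwise GCS points alone.
    """

    def __init__(self, data: pd.DataFrame, death_col: str = "death",
                 apm_col: str = "apm_mm", control_cols: list[str] | None = None):
        required = {apm_col, "apache2", "apache3", "gcs", death_col}
        missing = required - set(data.columns)
        if missing:
            raise ValidationError(f"cohort is missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True).copy()
        self.death_col = death_col
        self.apm_col = apm_col
        if set(self.data[death_col].unique()) != {0, 1}:
            raise ValidationError("cohort must contain both survivors and deaths")
        if "gcs_pts" not in self.data.columns:
            self.data["gcs_pts"] = 15 - self.data["gcs"]
        if control_cols is None:
            control_cols = sorted(
                (c for c in self.data.columns if c.startswith("phys_pts_")),
                key=lambda c: int(c.rsplit("_", 1)[1]))
        self.control_cols = list(control_cols)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "ApmApacheModel":
        return cls(data, **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "ApmApacheModel":
        from .io import read_cohort

        return cls(read_cohort(path), **kw)

    # ------------------------------------------------------------------
    def fit(self, weight_source: str = "derive",
            derivations: tuple[str, ...] = ("linear", "categorical"),
            rel_tol: float = 0.25, anchor: int | None = None,
            cutpoints: tuple[float, float] | None = None,
            rounding: str = "half_away",
            ci_level: float = 0.95) -> "ApmApacheResults":
        """Derive APM weighting rules and evaluate all scores.

        ``weight_source="derive"`` fits both rules from the data;
        ``"paper_default"`` skips the categorical derivation and applies the
        shipped (40, 7, 0) weights at cutpoints (10, 15).
        """
        if weight_source not in ("derive", "paper_default"):
            raise ValidationError(f"unknown weight source {weight_source!r}")
        df = self.data
        t = df[self.apm_col]
        y = df[self.death_col].to_numpy()
        median = float(np.median(t))
        anchor_val = int(anchor) if anchor is not None else int(round(median))

        # -- linear rule: multivariable APM fit, closeness to GCS ----------
        controls = ["gcs_pts"] + self.control_cols
        mv_fit = derive.fit_logistic(
            y, df[[self.apm_col] + controls], ci_level=ci_level)
        closeness = derive.compare_coefficients(
            mv_fit, self.apm_col, "gcs_pts", rel_tol=rel_tol)
        linear_rule = None
        linear_info: dict = {}
        if "linear" in derivations:
            linear_rule, linear_info = derive.derive_linear_rule(
                closeness, anchor=anchor_val)

        # -- risk curve, breakpoints, categorical weights ------------------
        curve = derive.estimate_risk_curve(
            df, apm_col=self.apm_col, death_col=self.death_col)
        categorical_rule = None
        cat_fit = None
        bp = None
        if weight_source == "paper_default":
            categorical_rule = PAPER_DEFAULT_WEIGHTS
            bp = PAPER_DEFAULT_WEIGHTS.cutpoints
        elif "categorical" in derivations:
            bp, bp_prov = derive.select_breakpoints(
                curve, median, override=cutpoints)
            cats = t.map(lambda v: severity.apm_category(v, cutpoints=bp))
            ind = pd.DataFrame({
                "apm_high": (cats == severity.ApmCategory.HIGH).astype(float),
                "apm_mid": (cats == severity.ApmCategory.MID).astype(float),
            })
            for col in ind.columns:
                if ind[col].sum() == 0:
                    raise ValidationError(
                        f"empty APM category for indicator '{col}' at "
                        f"cutpoints {bp}: cannot derive categorical weights")
            cat_fit = derive.fit_logistic(y, ind, ci_level=ci_level)
            categorical_rule = derive.derive_category_weights(
                cat_fit, cutpoints=bp, rounding=rounding)

        # -- composite scores ----------------------------------------------
        lin_for_scoring = linear_rule or WeightRule(
            kind="linear_anchor", anchor=anchor_val, provenance="paper_default")
        scored = df.copy()
        scored["apache2_apm"] = [
            severity.composite_ii(a, tt, anchor=lin_for_scoring.anchor)
            for a, tt in zip(df["apache2"], t)]
        cat_for_scoring = categorical_rule or PAPER_DEFAULT_WEIGHTS
        scored["apache3_apm"] = [
            severity.composite_iii(a, tt, weights=cat_for_scoring)
            for a, tt in zip(df["apache3"], t)]

        score_names = [self.apm_col, "apache2", "apache2_apm",
                       "apache3", "apache3_apm"]
        table2 = evaluate.or_per_point_table(
            scored, score_names, death_col=self.death_col, ci_level=ci_level)
        rocs = {name: evaluate.auc(scored[name], y, name=name,
                                   ci_level=ci_level)
                for name in score_names}
        comparisons = [
            evaluate.delong_compare(scored["apache2_apm"], scored["apache2"],
                                    y, "apache2_apm", "apache2"),
            evaluate.delong_compare(scored["apache3_apm"], scored["apache3"],
                                    y, "apache3_apm", "apache3"),
        ]
        return ApmApacheResults(
            model=self, scored=scored, mv_fit=mv_fit, closeness=closeness,
            linear_rule=linear_rule, linear_info=linear_info,
            risk_curve=curve, cutpoints=bp, categorical_fit=cat_fit,
            categorical_rule=categorical_rule, table2=table2, rocs=rocs,
            comparisons=comparisons, ci_level=ci_level,
            apm_median=median, weight_source=weight_source)


@dataclass
class ApmApacheResults:
    """Fitted rules, evaluation tables and diagnostics for one cohort."""

    model: ApmApacheModel
    scored: pd.DataFrame
    mv_fit: derive.LogisticFit
    closeness: derive.CoefficientComparison
    linear_rule: WeightRule | None
    linear_info: dict
    risk_curve: derive.RiskCurve
    cutpoints: tuple[float, float] | None
    categorical_fit: derive.LogisticFit | None
    categorical_rule: WeightRule | None
    table2: pd.DataFrame
    rocs: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    ci_level: float = 0.95
    apm_median: float = 15.0
    weight_source: str = "derive"

    def summary_table(self, grouping: str = "survivor-status") -> pd.DataFrame:
        """Grouped descriptive table (Table 1 / Table 3 analogue)."""
        return evaluate.cohort_summary(self.scored, grouping=grouping)

    def crude_category_ors(self) -> pd.DataFrame:
        """2x2 cross-product odds ratios per APM category vs the reference.

        Reported alongside the fitted ORs because printed category ORs in
        small cohorts are sensitive to the estimation sample.
        """
        cp = self.cutpoints or PAPER_DEFAULT_WEIGHTS.cutpoints
        cats = self.scored[self.model.apm_col].map(
            lambda v: severity.apm_category(v, cutpoints=cp).value)
        y = self.scored[self.model.death_col]
        ref_d = ((cats == "ref") & (y == 1)).sum()
        ref_a = ((cats == "ref") & (y == 0)).sum()
        rows = []
        for cat in ("high", "mid"):
            d = ((cats == cat) & (y == 1)).sum()
            a = ((cats == cat) & (y == 0)).sum()
            orv = (d * ref_a) / (a * ref_d) if a * ref_d > 0 else np.inf
            rows.append({"category": cat, "deaths": int(d), "alive": int(a),
                         "crude_or": float(orv)})
        rows.append({"category": "ref", "deaths": int(ref_d),
                     "alive": int(ref_a), "crude_or": 1.0})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        """Machine-readable derivation report."""
        def rule_dict(rule: WeightRule | None):
            if rule is None:
                return None
            return {"kind": rule.kind, "anchor": rule.anchor,
                    "cutpoints": list(rule.cutpoints),
                    "weights": list(rule.weights),
                    "provenance": rule.provenance}

        return {
            "n": int(len(self.scored)),
            "apm_median": self.apm_median,
            "closeness": {
                "close": self.closeness.close,
                "b_apm": self.closeness.b_a,
                "b_gcs": self.closeness.b_b,
                "ratio": self.closeness.ratio,
                "rel_tol": self.closeness.rel_tol,
            },
            "linear_rule": rule_dict(self.linear_rule),
            "categorical_rule": rule_dict(self.categorical_rule),
            "cutpoints": list(self.cutpoints) if self.cutpoints else None,
            "weight_source": self.weight_source,
            "multivariable_fit": self.mv_fit.summary_frame().to_dict("index"),
            "table2": self.table2.to_dict("records"),
            "delong": [
                {"a": c.name_a, "b": c.name_b, "auc_a": c.auc_a,
                 "auc_b": c.auc_b, "delta": c.delta, "z": c.z, "p": c.pvalue}
                for c in self.comparisons
            ],
        }

    def summary(self) -> str:
        """Human-readable report of the derivation and model comparison."""
        lines = ["Composite APACHE-APM model results",
                 "=" * 50,
                 f"patients: {len(self.scored)}   "
                 f"deaths: {int(self.scored[self.model.death_col].sum())}",
                 f"APM median: {self.apm_median:g} mm",
                 "",
                 "APM vs GCS coefficient check (multivariable fit):",
                 f"  B_apm={self.closeness.b_a:+.4f}/mm  "
                 f"B_gcs={self.closeness.b_b:+.4f}/pt  "
                 f"close={self.closeness.close} "
                 f"(rel_tol={self.closeness.rel_tol})"]
        if self.linear_rule is not None:
            lines.append(f"  linear rule: score(t) = max(0, "
                         f"{self.linear_rule.anchor} - t)  "
                         f"[{self.linear_rule.provenance}]")
        else:
            lines.append("  linear rule: not emitted")
        if self.categorical_rule is not None:
            r = self.categorical_rule
            lines += ["",
                      f"categorical rule [{r.provenance}]: cutpoints "
                      f"{r.cutpoints}, weights HIGH={r.weights[0]} "
                      f"MID={r.weights[1]} REF=0"]
        lines += ["", "per-point odds ratios and AUCs:",
                  self.table2.to_string(index=False,
                                        float_format=lambda x: f"{x:.4f}")]
        lines += ["", "paired DeLong comparisons:"]
        for c in self.comparisons:
            lines.append(f"  {c.name_a} vs {c.name_b}: "
                         f"dAUC={c.delta:+.4f}  z={c.z:.3f}  p={c.pvalue:.4f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Overlay ROC curves for all evaluated scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for roc in self.rocs.values():
            roc.plot(ax=ax)
        return ax
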