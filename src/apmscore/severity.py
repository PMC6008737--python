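"""APACHE II scoring engine, APM thickness points and the two composite scores.

The APACHE II acute physiology score is table-driven: each physiologic
variable carries a piecewise interval -> points mapping (0-4 points per
variable), shipped as a versioned, checksummed YAML file transcribed from the
original Knaus score sheet.  The engine applies the worst-value-in-24h rule,
adds Glasgow Coma Scale points (15 - GCS), age points and chronic-health
points, for a total in [0, 71].

Adductor pollicis muscle (APM) thickness enters either through the linear
anchor rule ``max(0, 15 - t)`` (added to APACHE II, composite range 0-86) or
through three risk categories with integer weights (added to APACHE III,
composite range 0-339).
"""

from __future__ import annotations

import enum
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ApmCategory",
    "ChronicHealth",
    "ApmMeasurement",
    "OxygenationReading",
    "PhysiologyPanel",
    "ScoreTable",
    "ScoreBreakdown",
    "Apache3Score",
    "PatientRecord",
    "WeightRule",
    "PAPER_DEFAULT_WEIGHTS",
    "ValidationError",
    "average_apm",
    "apm_points",
    "apm_category",
    "apm_category_points",
    "worst_value",
    "score_apache2",
    "composite_ii",
    "composite_iii",
    "load_score_tables",
    "APACHE2_TABLES_SHA256",
    "APACHE2_MAX",
    "APACHE3_MAX",
    "COMPOSITE_II_MAX",
    "COMPOSITE_III_MAX",
]

APACHE2_MAX = 71
APACHE3_MAX = 299
COMPOSITE_II_MAX = 86
COMPOSITE_III_MAX = 339

#: SHA-256 of the shipped APACHE II score-table file; verified on load so a
#: silently edited table cannot masquerade as the transcribed original.
APACHE2_TABLES_SHA256 = "39a2f25d143ba0404914861626ba0c94346d5196c41e0e1f7e49af0e9d1bf960"


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class ApmCategory(enum.Enum):
    """APM thickness risk category (HIGH risk = thinnest muscle)."""

    HIGH = "high"  # t <= 10 mm
    MID = "mid"    # 10 < t <= 15 mm
    REF = "ref"    # t > 15 mm (reference)


class ChronicHealth(enum.Enum):
    """APACHE II chronic-health state (severe organ insufficiency history)."""

    NONE = "none"
    NONOPERATIVE_OR_EMERGENCY_POSTOP = "nonoperative_or_emergency_postop"
    ELECTIVE_POSTOP = "elective_postop"


CHRONIC_HEALTH_POINTS = {
    ChronicHealth.NONE: 0,
    ChronicHealth.NONOPERATIVE_OR_EMERGENCY_POSTOP: 5,
    ChronicHealth.ELECTIVE_POSTOP: 2,
}

# (lower age bound, points); highest band wins.
AGE_POINTS_BANDS = [(75, 6), (65, 5), (55, 3), (45, 2), (0, 0)]


def age_points(age: float) -> int:
    if age < 16:
        raise ValidationError(f"age {age} below study inclusion minimum of 16")
    for low, pts in AGE_POINTS_BANDS:
        if age >= low:
            return pts
    raise AssertionError("unreachable")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (APACHE point style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApmMeasurement:
    """Three consecutive caliper readings of APM thickness (mm), dominant hand."""

    readings: tuple[float, float, float]
    dominant_hand: bool = True

    def __post_init__(self) -> None:
        if len(self.readings) != 3:
            raise ValidationError(
                f"APM measurement requires exactly 3 readings, got {len(self.readings)}"
            )
        for r in self.readings:
            if not (0 < r < 60):
                raise ValidationError(f"APM reading {r} mm outside (0, 60) mm")


@dataclass(frozen=True)
class OxygenationReading:
    """One oxygenation observation; scored on A-aDO2 if FiO2 >= 0.5, else PaO2."""

    fio2: float
    pao2: float | None = None
    aado2: float | None = None

    def __post_init__(self) -> None:
        if not (0.21 <= self.fio2 <= 1.0):
            raise ValidationError(f"FiO2 {self.fio2} outside [0.21, 1.0]")
        if self.fio2 >= 0.5 and self.aado2 is None:
            raise ValidationError("FiO2 >= 0.5 requires an A-aDO2 value")
        if self.fio2 < 0.5 and self.pao2 is None:
            raise ValidationError("FiO2 < 0.5 requires a PaO2 value")


#: The 10 plain interval-scored APACHE II variables (oxygenation and GCS are special).
PLAIN_VARIABLES = (
    "temperature",
    "mean_arterial_pressure",
    "heart_rate",
    "respiratory_rate",
    "arterial_ph",
    "sodium",
    "potassium",
    "creatinine",
    "hematocrit",
    "white_cell_count",
)


@dataclass
class PhysiologyPanel:
    """Worst-of-24h input panel for the 12 APACHE II physiologic variables.

    ``series`` maps each plain variable name to its (time-ordered) readings;
    oxygenation readings carry the FiO2 branch, and GCS is a single integer
    (the worst GCS is conventionally recorded directly).
    """

    series: Mapping[str, Sequence[float]]
    oxygenation: Sequence[OxygenationReading]
    gcs: int
    age: float
    chronic_health: ChronicHealth = ChronicHealth.NONE
    acute_renal_failure: bool = False

    def __post_init__(self) -> None:
        if not (3 <= self.gcs <= 15) or int(self.gcs) != self.gcs:
            raise ValidationError(f"GCS {self.gcs} must be an integer in [3, 15]")
        if self.age < 16:
            raise ValidationError(f"age {self.age} below study inclusion minimum of 16")
        if len(self.oxygenation) == 0:
            raise ValidationError("empty series for variable 'oxygenation'")
        for name in PLAIN_VARIABLES:
            if name not in self.series:
                raise ValidationError(f"missing physiologic variable '{name}'")
            if len(self.series[name]) == 0:
                raise ValidationError(f"empty series for variable '{name}'")


@dataclass(frozen=True)
class Interval:
    low: float
    high: float
    points: int


@dataclass
class ScoreTable:
    """Piecewise interval -> points mapping for one physiologic variable.

    Intervals are half-open ``[low, high)``; the highest interval is closed at
    the top of the domain.  Exactly one interval carries 0 points.
    """

    variable: str
    unit: str
    domain: tuple[float, float]
    intervals: list[Interval]
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.low)
        lo, hi = self.domain
        if not ivs or ivs[0].low != lo or ivs[-1].high != hi:
            raise ValidationError(
                f"{self.variable}: intervals do not span domain [{lo}, {hi}]"
            )
        for a, b in zip(ivs, ivs[1:]):
            if a.high != b.low:
                raise ValidationError(
                    f"{self.variable}: gap/overlap between {a.high} and {b.low}"
                )
        if any(iv.points < 0 for iv in ivs):
            raise ValidationError(f"{self.variable}: negative points")
        if sum(1 for iv in ivs if iv.points == 0) != 1:
            raise ValidationError(f"{self.variable}: must have exactly one 0-point band")
        self.intervals = ivs

    @property
    def zero_band(self) -> Interval:
        return next(iv for iv in self.intervals if iv.points == 0)

    @property
    def max_points(self) -> int:
        return max(iv.points for iv in self.intervals)

    def points(self, value: float) -> int:
        lo, hi = self.domain
        v = min(max(value, lo), hi)  # out-of-domain readings clamp to the extreme band
        for iv in self.intervals:
            if iv.low <= v < iv.high:
                return iv.points
        return self.intervals[-1].points  # v == domain top (closed)


@dataclass
class ScoreBreakdown:
    """Per-component APACHE II points and their total."""

    variable_points: dict[str, int]
    gcs_points: int
    age_points: int
    chronic_points: int

    @property
    def acute_physiology(self) -> int:
        return sum(self.variable_points.values()) + self.gcs_points

    @property
    def total(self) -> int:
        return self.acute_physiology + self.age_points + self.chronic_points

    def __post_init__(self) -> None:
        if not (0 <= self.total <= APACHE2_MAX):
            raise ValidationError(f"APACHE II total {self.total} outside [0, {APACHE2_MAX}]")


@dataclass(frozen=True)
class Apache3Score:
    """A validated APACHE III total (components optional; engine out of scope)."""

    total: int
    acute_physiology: int | None = None
    age: int | None = None
    chronic_health: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.total <= APACHE3_MAX):
            raise ValidationError(f"APACHE III total {self.total} outside [0, {APACHE3_MAX}]")
        comps = (self.acute_physiology, self.age, self.chronic_health)
        if any(c is not None for c in comps):
            if any(c is None for c in comps):
                raise ValidationError("APACHE III components must be all present or all absent")
            ap, ag, ch = comps
            if not (0 <= ap <= 252):
                raise ValidationError(f"APACHE III acute physiology {ap} outside [0, 252]")
            if not (0 <= ag <= 24):
                raise ValidationError(f"APACHE III age score {ag} outside [0, 24]")
            if not (0 <= ch <= 23):
                raise ValidationError(f"APACHE III chronic health {ch} outside [0, 23]")
            if ap + ag + ch != self.total:
                raise ValidationError("APACHE III components do not sum to total")


@dataclass
class PatientRecord:
    """One patient: averaged APM thickness, severity totals, outcome, covariates."""

    id: str
    apm_mm: float
    apache2: int
    apache3: int
    gcs: int
    death: int
    panel: PhysiologyPanel | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.apm_mm <= 40):
            raise ValidationError(f"APM thickness {self.apm_mm} mm outside [1, 40]")
        if self.death not in (0, 1):
            raise ValidationError(f"death indicator {self.death} not in {{0, 1}}")
        if not (0 <= self.apache2 <= APACHE2_MAX):
            raise ValidationError(f"APACHE II {self.apache2} outside [0, {APACHE2_MAX}]")
        if not (0 <= self.apache3 <= APACHE3_MAX):
            raise ValidationError(f"APACHE III {self.apache3} outside [0, {APACHE3_MAX}]")
        if not (3 <= self.gcs <= 15):
            raise ValidationError(f"GCS {self.gcs} outside [3, 15]")


@dataclass(frozen=True)
class WeightRule:
    """A derived APM weighting.

    ``linear_anchor``: score(t) = max(0, anchor - round(t)); ``categorical``:
    integer weights per thickness category (HIGH, MID, REF) with strictly
    increasing cutpoints and reference weight 0.
    """

    kind: str  # "linear_anchor" | "categorical"
    anchor: int = 15
    cutpoints: tuple[float, float] = (10.0, 15.0)
    weights: tuple[int, int, int] = (40, 7, 0)
    provenance: str = "paper_default"  # "fitted" | "paper_default" | "manual"

    def __post_init__(self) -> None:
        if self.kind not in ("linear_anchor", "categorical"):
            raise ValidationError(f"unknown WeightRule kind {self.kind!r}")
        if self.kind == "categorical":
            if self.cutpoints[0] >= self.cutpoints[1]:
                raise ValidationError("cutpoints must be strictly increasing")
            if any(w < 0 or int(w) != w for w in self.weights):
                raise ValidationError("category weights must be non-negative integers")
            if self.weights[2] != 0:
                raise ValidationError("reference category weight must be 0")

    @property
    def max_points(self) -> int:
        """Largest number of points the rule can award."""
        return self.anchor if self.kind == "linear_anchor" else max(self.weights)

    def points(self, t: float) -> int:
        if self.kind == "linear_anchor":
            return apm_points(t, anchor=self.anchor)
        return apm_category_points(apm_category(t, cutpoints=self.cutpoints), self)


#: Category weights as printed in the study (never re-derived from its tables).
PAPER_DEFAULT_WEIGHTS = WeightRule(kind="categorical", provenance="paper_default")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def average_apm(m: ApmMeasurement, rounding: str = "half_away") -> tuple[float, int]:
    """Average the three APM readings.

    Returns ``(raw_mean, rounded_mm)``; the integer value feeds the scoring
    rules, the raw mean is retained for the risk-curve stage.

    ``rounding``: ``"half_away"`` (default) or ``"none"`` (rounded value is the
    raw mean truncated to the same float — callers opting out of rounding).
    """
    raw = sum(m.readings) / 3.0
    if rounding == "half_away":
        return raw, round_half_away(raw)
    if rounding == "none":
        return raw, raw  # type: ignore[return-value]
    raise ValidationError(f"unknown rounding mode {rounding!r}")


def apm_points(t: float, anchor: int = 15, rounding: str = "half_away") -> int:
    """Linear anchor rule: points = max(0, anchor - t) after integer rounding of t."""
    if t <= 0:
        raise ValidationError(f"APM thickness {t} must be positive")
    ti = round_half_away(t) if rounding == "half_away" else t
    return max(0, int(anchor - ti))


def apm_category(t: float, cutpoints: tuple[float, float] = (10.0, 15.0)) -> ApmCategory:
    """Thickness category: HIGH (t <= lower), MID (lower < t <= upper), REF (t > upper)."""
    if t <= 0:
        raise ValidationError(f"APM thickness {t} must be positive")
    lower, upper = cutpoints
    if t <= lower:
        return ApmCategory.HIGH
    if t <= upper:
        return ApmCategory.MID
    return ApmCategory.REF


def apm_category_points(c: ApmCategory, weights: WeightRule) -> int:
    if weights.kind != "categorical":
        raise ValidationError("category points require a categorical WeightRule")
    mapping = {
        ApmCategory.HIGH: weights.weights[0],
        ApmCategory.MID: weights.weights[1],
        ApmCategory.REF: weights.weights[2],
    }
    try:
        return mapping[c]
    except KeyError:  # pragma: no cover - enum exhaustiveness
        raise ValidationError(f"unknown APM category {c!r}") from None


def worst_value(series: Sequence[float], table: ScoreTable) -> float:
    """The reading attaining maximal points under ``table``.

    Ties are broken toward the value farthest from the midpoint of the
    zero-point (normal) band, then toward the earliest reading.
    """
    if len(series) == 0:
        raise ValidationError(f"empty series for variable '{table.variable}'")
    zb = table.zero_band
    mid = 0.5 * (zb.low + zb.high)
    best = None  # (points, distance, -index) maximised
    best_val = None
    for i, v in enumerate(series):
        key = (table.points(v), abs(v - mid), -i)
        if best is None or key > best:
            best = key
            best_val = v
    return best_val


def _oxygenation_points(readings: Sequence[OxygenationReading],
                        tables: Mapping[str, ScoreTable]) -> int:
    pts = []
    for r in readings:
        if r.fio2 >= 0.5:
            pts.append(tables["aado2"].points(r.aado2))
        else:
            pts.append(tables["pao2"].points(r.pao2))
    return max(pts)


def score_apache2(panel: PhysiologyPanel,
                  tables: Mapping[str, ScoreTable] | None = None) -> ScoreBreakdown:
    """Score a full panel: worst-value points per variable + GCS + age + chronic.

    Creatinine points are doubled under acute renal failure.  Missing
    variables raise (no silent normal-imputation); ``PhysiologyPanel`` already
    enforces presence, so this guards externally-constructed mappings too.
    """
    if tables is None:
        tables = load_score_tables()
    var_pts: dict[str, int] = {}
    for name in PLAIN_VARIABLES:
        if name not in tables:
            raise ValidationError(f"no score table for variable '{name}'")
        tab = tables[name]
        wv = worst_value(panel.series[name], tab)
        p = tab.points(wv)
        if name == "creatinine" and panel.acute_renal_failure \
                and "double_if_acute_renal_failure" in tab.modifiers:
            p *= 2
        var_pts[name] = p
    var_pts["oxygenation"] = _oxygenation_points(panel.oxygenation, tables)
    return ScoreBreakdown(
        variable_points=var_pts,
        gcs_points=15 - panel.gcs,
        age_points=age_points(panel.age),
        chronic_points=CHRONIC_HEALTH_POINTS[panel.chronic_health],
    )


def composite_ii(apache2: int, t: float, anchor: int = 15) -> int:
    """Composite APACHE II-APM: APACHE II total plus linear-rule APM points (0-86)."""
    if not (0 <= apache2 <= APACHE2_MAX):
        raise ValidationError(f"APACHE II {apache2} outside [0, {APACHE2_MAX}]")
    return int(apache2) + apm_points(t, anchor=anchor)


def composite_iii(apache3: int, t: float,
                  weights: WeightRule = PAPER_DEFAULT_WEIGHTS) -> int:
    """Composite APACHE III-APM: APACHE III total plus category weight (0-339)."""
    if not (0 <= apache3 <= APACHE3_MAX):
        raise ValidationError(f"APACHE III {apache3} outside [0, {APACHE3_MAX}]")
    return int(apache3) + apm_category_points(
        apm_category(t, cutpoints=weights.cutpoints), weights
    )


# ---------------------------------------------------------------------------
# score-table loading
# ---------------------------------------------------------------------------

def _tables_text() -> str:
    return (resources.files("apmscore") / "data" / "apache2_tables.yaml").read_text()


def load_score_tables(verify_checksum: bool = True) -> dict[str, ScoreTable]:
    """Load the shipped APACHE II score tables, verifying the recorded SHA-256."""
    text = _tables_text()
    if verify_checksum:
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != APACHE2_TABLES_SHA256:
            raise ValidationError(
                "apache2_tables.yaml checksum mismatch: "
                f"expected {APACHE2_TABLES_SHA256}, got {digest}"
            )
    doc = yaml.safe_load(text)
    tables: dict[str, ScoreTable] = {}
    for entry in doc["variables"]:
        tables[entry["variable"]] = ScoreTable(
            variable=entry["variable"],
            unit=entry["unit"],
            domain=tuple(entry["domain"]),
            intervals=[Interval(**iv) for iv in entry["intervals"]],
            modifiers=tuple(entry.get("modifiers", ())),
        )
    return tables
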