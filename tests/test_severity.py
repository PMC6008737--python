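"""APACHE II engine, APM points/categories and composite score behaviour."""

import hashlib

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmscore import severity
from apmscore.severity import (
    APACHE2_TABLES_SHA256,
    PAPER_DEFAULT_WEIGHTS,
    Apache3Score,
    ApmCategory,
    ApmMeasurement,
    ChronicHealth,
    Interval,
    OxygenationReading,
    PatientRecord,
    PhysiologyPanel,
    ScoreTable,
    ValidationError,
    WeightRule,
    apm_category,
    apm_category_points,
    apm_points,
    average_apm,
    composite_ii,
    composite_iii,
    load_score_tables,
    score_apache2,
    worst_value,
)
from apmscore.simulate import _template_panel


# ---------------------------------------------------------------------------
# APM averaging and points
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("readings, raw, rounded", [
    ((15, 15, 15), 15.0, 15),
    ((14, 15, 16), 15.0, 15),
    ((12.0, 12.5, 13.0), 12.5, 13),   # half rounds away from zero
])
def test_average_apm(readings, raw, rounded):
    got_raw, got_round = average_apm(ApmMeasurement(readings))
    assert got_raw == pytest.approx(raw)
    assert got_round == rounded


def test_average_apm_requires_three_readings():
    with pytest.raises(ValidationError, match="3 readings"):
        ApmMeasurement((12, 13))
    with pytest.raises(ValidationError, match="outside"):
        ApmMeasurement((12, 13, 65))


@pytest.mark.parametrize("t, pts", [(12, 3), (15, 0), (21, 0), (6, 9), (1, 14)])
def test_apm_points_linear_rule(t, pts):
    assert apm_points(t) == pts


def test_apm_points_rejects_nonpositive():
    with pytest.raises(ValidationError):
        apm_points(0)
    with pytest.raises(ValidationError):
        apm_points(-3)


@given(st.integers(min_value=1, max_value=40))
@settings(max_examples=50, deadline=None)
def test_apm_points_monotone_unit_steps(t):
    """Non-increasing in t, zero beyond 15 mm, unit decrements on integers."""
    assert apm_points(t) >= apm_points(t + 1)
    assert apm_points(t) - apm_points(t + 1) in (0, 1)
    if t >= 15:
        assert apm_points(t) == 0


@pytest.mark.parametrize("t, cat", [
    (10, ApmCategory.HIGH),      # boundary belongs to the thin group
    (15, ApmCategory.MID),       # (10, 15] read as mid
    (15.5, ApmCategory.REF),
    (6, ApmCategory.HIGH),
    (21, ApmCategory.REF),
])
def test_apm_category_boundaries(t, cat):
    assert apm_category(t) == cat


@given(st.floats(min_value=0.5, max_value=45, allow_nan=False))
@settings(max_examples=100, deadline=None)
def test_apm_category_partitions(t):
    """Every positive thickness maps to exactly one category."""
    cat = apm_category(t)
    assert cat in (ApmCategory.HIGH, ApmCategory.MID, ApmCategory.REF)
    pts = apm_category_points(cat, PAPER_DEFAULT_WEIGHTS)
    # category points non-increasing in thickness
    assert pts == {ApmCategory.HIGH: 40, ApmCategory.MID: 7,
                   ApmCategory.REF: 0}[cat]


def test_category_points_require_categorical_rule():
    linear = WeightRule(kind="linear_anchor")
    with pytest.raises(ValidationError):
        apm_category_points(ApmCategory.HIGH, linear)


# ---------------------------------------------------------------------------
# worst-value rule
# ---------------------------------------------------------------------------

def test_worst_value_rules(score_tables):
    hr = score_tables["heart_rate"]
    assert worst_value([88.0], hr) == 88.0
    # 185 scores 4 points, 45 scores 3 -> pick 185
    assert worst_value([45.0, 185.0], hr) == 185.0
    # both in zero band (70-110, midpoint 90): farther from midpoint wins
    assert worst_value([85.0, 105.0], hr) == 105.0
    # exact tie in points and distance: earliest reading wins
    assert worst_value([94.5, 85.5], hr) == 94.5
    with pytest.raises(ValidationError):
        worst_value([], hr)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

def test_tables_cover_all_variables(score_tables):
    assert set(severity.PLAIN_VARIABLES) <= set(score_tables)
    assert {"pao2", "aado2"} <= set(score_tables)
    for tab in score_tables.values():
        assert tab.max_points <= 4
        assert tab.zero_band.points == 0


def test_table_checksum_matches_file():
    from apmscore.severity import _tables_text

    assert hashlib.sha256(_tables_text().encode()).hexdigest() == APACHE2_TABLES_SHA256


def test_tampered_table_file_rejected(monkeypatch):
    monkeypatch.setattr(severity, "_tables_text",
                        lambda: "version: x\nvariables: []\n")
    with pytest.raises(ValidationError, match="checksum"):
        load_score_tables()


def test_score_table_partition_invariants():
    with pytest.raises(ValidationError, match="gap"):
        ScoreTable("v", "u", (0, 10), [Interval(0, 4, 1), Interval(5, 10, 0)])
    with pytest.raises(ValidationError, match="0-point"):
        ScoreTable("v", "u", (0, 10), [Interval(0, 5, 0), Interval(5, 10, 0)])
    with pytest.raises(ValidationError, match="span"):
        ScoreTable("v", "u", (0, 10), [Interval(0, 5, 0), Interval(5, 9, 2)])


# ---------------------------------------------------------------------------
# full APACHE II scoring
# ---------------------------------------------------------------------------

def test_all_normal_panel_scores_zero(score_tables):
    bd = score_apache2(_template_panel("all_normal"), score_tables)
    assert bd.acute_physiology == 0
    assert bd.total == 0


def test_gcs_contributes_fifteen_minus_gcs(score_tables):
    panel = _template_panel("all_normal")
    panel.gcs = 3
    bd = score_apache2(panel, score_tables)
    assert bd.gcs_points == 12
    assert bd.total == 12


def test_all_worst_panel_reaches_engine_maximum(score_tables):
    bd = score_apache2(_template_panel("all_worst"), score_tables)
    assert bd.variable_points["creatinine"] == 8  # doubled under renal failure
    assert bd.age_points == 6 and bd.chronic_points == 5
    assert bd.total == severity.APACHE2_MAX == 71


def test_arf_flag_doubles_creatinine_only(score_tables):
    panel = _template_panel("all_normal")
    panel.series = {**panel.series, "creatinine": [4.0]}
    no_arf = score_apache2(panel, score_tables).total
    panel.acute_renal_failure = True
    with_arf = score_apache2(panel, score_tables).total
    assert no_arf == 4 and with_arf == 8


def test_missing_variable_is_named():
    series = {k: [v] for k, v in {
        "temperature": 37.0, "mean_arterial_pressure": 90.0, "heart_rate": 80.0,
        "respiratory_rate": 16.0, "arterial_ph": 7.4, "sodium": 140.0,
        "potassium": 4.0, "creatinine": 1.0, "hematocrit": 40.0}.items()}
    with pytest.raises(ValidationError, match="white_cell_count"):
        PhysiologyPanel(series=series,
                        oxygenation=[OxygenationReading(fio2=0.3, pao2=90.0)],
                        gcs=15, age=30)


def test_oxygenation_branch_by_fio2(score_tables):
    panel = _template_panel("all_normal")
    # high FiO2 -> A-aDO2 table (400 -> 3 points)
    panel.oxygenation = [OxygenationReading(fio2=0.8, aado2=400.0)]
    assert score_apache2(panel, score_tables).variable_points["oxygenation"] == 3
    # low FiO2 -> PaO2 table (58 -> 3 points)
    panel.oxygenation = [OxygenationReading(fio2=0.3, pao2=58.0)]
    assert score_apache2(panel, score_tables).variable_points["oxygenation"] == 3


def test_engine_matches_bruteforce_oracle(score_tables):
    from apmscore.simulate import generate_physiology_fixtures

    for panel, expected in generate_physiology_fixtures(100, seed=42,
                                                        tables=score_tables):
        assert score_apache2(panel, score_tables).total == expected


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a2, t, expected", [(20, 13, 22), (0, 21, 0), (71, 1, 85)])
def test_composite_ii(a2, t, expected):
    assert composite_ii(a2, t) == expected


def test_composite_ii_maximum_is_86():
    rule = WeightRule(kind="linear_anchor", anchor=15)
    assert severity.APACHE2_MAX + rule.max_points == severity.COMPOSITE_II_MAX == 86
    assert composite_ii(71, 0.4) == 86  # sub-mm thickness rounds to zero


@pytest.mark.parametrize("a3, t, expected", [(70, 10, 110), (299, 8, 339), (47, 16, 47)])
def test_composite_iii(a3, t, expected):
    assert composite_iii(a3, t) == expected


def test_composite_range_validation():
    with pytest.raises(ValidationError):
        composite_ii(72, 15)
    with pytest.raises(ValidationError):
        composite_iii(300, 15)


@given(st.integers(min_value=0, max_value=71),
       st.floats(min_value=1, max_value=40, allow_nan=False))
@settings(max_examples=100, deadline=None)
def test_adding_apm_never_lowers_a_score(a, t):
    assert composite_ii(a, t) >= a
    a3 = min(a * 4, 299)
    assert composite_iii(a3, t) >= a3


# ---------------------------------------------------------------------------
# validated record types
# ---------------------------------------------------------------------------

def test_apache3_component_validation():
    Apache3Score(total=100, acute_physiology=80, age=10, chronic_health=10)
    with pytest.raises(ValidationError, match="sum"):
        Apache3Score(total=100, acute_physiology=80, age=10, chronic_health=5)
    with pytest.raises(ValidationError, match="outside"):
        Apache3Score(total=300)
    with pytest.raises(ValidationError, match="age"):
        Apache3Score(total=100, acute_physiology=70, age=25, chronic_health=5)


def test_patient_record_validation():
    rec = PatientRecord(id="p1", apm_mm=15, apache2=15, apache3=47, gcs=14, death=0)
    assert rec.apm_mm == 15
    with pytest.raises(ValidationError):
        PatientRecord(id="p2", apm_mm=0.5, apache2=15, apache3=47, gcs=14, death=0)
    with pytest.raises(ValidationError):
        PatientRecord(id="p3", apm_mm=15, apache2=15, apache3=47, gcs=14, death=2)
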