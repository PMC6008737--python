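# Acute Physiology Score bands for the APACHE II system (Knaus et al., 1985).
# Intervals are half-open [low, high); the highest interval of each variable is
# closed at the top of the declared domain. Exactly one interval per variable
# carries 0 points (the normal band).
version: apache2-aps-1985
variables:
  - variable: temperature
    unit: degC
    domain: [25.0, 46.0]
    intervals:
      - {low: 25.0, high: 30.0, points: 4}
      - {low: 30.0, high: 32.0, points: 3}
      - {low: 32.0, high: 34.0, points: 2}
      - {low: 34.0, high: 36.0, points: 1}
      - {low: 36.0, high: 38.5, points: 0}
      - {low: 38.5, high: 39.0, points: 1}
      - {low: 39.0, high: 41.0, points: 3}
      - {low: 41.0, high: 46.0, points: 4}
  - variable: mean_arterial_pressure
    unit: mmHg
    domain: [20.0, 250.0]
    intervals:
      - {low: 20.0, high: 50.0, points: 4}
      - {low: 50.0, high: 70.0, points: 2}
      - {low: 70.0, high: 110.0, points: 0}
      - {low: 110.0, high: 130.0, points: 2}
      - {low: 130.0, high: 160.0, points: 3}
      - {low: 160.0, high: 250.0, points: 4}
  - variable: heart_rate
    unit: /min
    domain: [20.0, 250.0]
    intervals:
      - {low: 20.0, high: 40.0, points: 4}
      - {low: 40.0, high: 55.0, points: 3}
      - {low: 55.0, high: 70.0, points: 2}
      - {low: 70.0, high: 110.0, points: 0}
      - {low: 110.0, high: 140.0, points: 2}
      - {low: 140.0, high: 180.0, points: 3}
      - {low: 180.0, high: 250.0, points: 4}
  - variable: respiratory_rate
    unit: /min
    domain: [0.0, 80.0]
    intervals:
      - {low: 0.0, high: 6.0, points: 4}
      - {low: 6.0, high: 10.0, points: 2}
      - {low: 10.0, high: 12.0, points: 1}
      - {low: 12.0, high: 25.0, points: 0}
      - {low: 25.0, high: 35.0, points: 1}
      - {low: 35.0, high: 50.0, points: 3}
      - {low: 50.0, high: 80.0, points: 4}
  # Oxygenation is scored on A-aDO2 when FiO2 >= 0.5 and on PaO2 otherwise;
  # the branch is applied per reading by the engine.
  - variable: aado2
    unit: mmHg
    domain: [0.0, 800.0]
    intervals:
      - {low: 0.0, high: 200.0, points: 0}
      - {low: 200.0, high: 350.0, points: 2}
      - {low: 350.0, high: 500.0, points: 3}
      - {low: 500.0, high: 800.0, points: 4}
  - variable: pao2
    unit: mmHg
    domain: [20.0, 700.0]
    intervals:
      - {low: 20.0, high: 55.0, points: 4}
      - {low: 55.0, high: 61.0, points: 3}
      - {low: 61.0, high: 71.0, points: 1}
      - {low: 71.0, high: 700.0, points: 0}
  - variable: arterial_ph
    unit: pH
    domain: [6.5, 8.0]
    intervals:
      - {low: 6.5, high: 7.15, points: 4}
      - {low: 7.15, high: 7.25, points: 3}
      - {low: 7.25, high: 7.33, points: 2}
      - {low: 7.33, high: 7.5, points: 0}
      - {low: 7.5, high: 7.6, points: 1}
      - {low: 7.6, high: 7.7, points: 3}
      - {low: 7.7, high: 8.0, points: 4}
  - variable: sodium
    unit: mmol/L
    domain: [90.0, 200.0]
    intervals:
      - {low: 90.0, high: 111.0, points: 4}
      - {low: 111.0, high: 120.0, points: 3}
      - {low: 120.0, high: 130.0, points: 2}
      - {low: 130.0, high: 150.0, points: 0}
      - {low: 150.0, high: 155.0, points: 1}
      - {low: 155.0, high: 160.0, points: 2}
      - {low: 160.0, high: 180.0, points: 3}
      - {low: 180.0, high: 200.0, points: 4}
  - variable: potassium
    unit: mmol/L
    domain: [1.0, 10.0]
    intervals:
      - {low: 1.0, high: 2.5, points: 4}
      - {low: 2.5, high: 3.0, points: 2}
      - {low: 3.0, high: 3.5, points: 1}
      - {low: 3.5, high: 5.5, points: 0}
      - {low: 5.5, high: 6.0, points: 1}
      - {low: 6.0, high: 7.0, points: 3}
      - {low: 7.0, high: 10.0, points: 4}
  - variable: creatinine
    unit: mg/dL
    domain: [0.1, 15.0]
    intervals:
      - {low: 0.1, high: 0.6, points: 2}
      - {low: 0.6, high: 1.5, points: 0}
      - {low: 1.5, high: 2.0, points: 2}
      - {low: 2.0, high: 3.5, points: 3}
      - {low: 3.5, high: 15.0, points: 4}
    modifiers: [double_if_acute_renal_failure]
  - variable: hematocrit
    unit: "%"
    domain: [5.0, 75.0]
    intervals:
      - {low: 5.0, high: 20.0, points: 4}
      - {low: 20.0, high: 30.0, points: 2}
      - {low: 30.0, high: 46.0, points: 0}
      - {low: 46.0, high: 50.0, points: 1}
      - {low: 50.0, high: 60.0, points: 2}
      - {low: 60.0, high: 75.0, points: 4}
  - variable: white_cell_count
    unit: 1e3/uL
    domain: [0.0, 100.0]
    intervals:
      - {low: 0.0, high: 1.0, points: 4}
      - {low: 1.0, high: 3.0, points: 2}
      - {low: 3.0, high: 15.0, points: 0}
      - {low: 15.0, high: 20.0, points: 1}
      - {low: 20.0, high: 40.0, points: 2}
      - {low: 40.0, high: 100.0, points: 4}
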