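# National Early Warning Score (Royal College of Physicians, 2012 chart).
# Bands are closed on both ends at chart precision (integers; temperature
# to 0.1 degC) and cover the full plausibility range of each vital.
system: NEWS
source: Royal College of Physicians NEWS chart (2012)
bands:
  - {component: resp_rate, lower: 0, upper: 8, points: 3}
  - {component: resp_rate, lower: 9, upper: 11, points: 1}
  - {component: resp_rate, lower: 12, upper: 20, points: 0}
  - {component: resp_rate, lower: 21, upper: 24, points: 2}
  - {component: resp_rate, lower: 25, upper: 80, points: 3}
  - {component: spo2, lower: 50, upper: 91, points: 3}
  - {component: spo2, lower: 92, upper: 93, points: 2}
  - {component: spo2, lower: 94, upper: 95, points: 1}
  - {component: spo2, lower: 96, upper: 100, points: 0}
  - {component: temperature, lower: 30.0, upper: 35.0, points: 3}
  - {component: temperature, lower: 35.1, upper: 36.0, points: 1}
  - {component: temperature, lower: 36.1, upper: 38.0, points: 0}
  - {component: temperature, lower: 38.1, upper: 39.0, points: 1}
  - {component: temperature, lower: 39.1, upper: 43.0, points: 2}
  - {component: systolic_bp, lower: 30, upper: 90, points: 3}
  - {component: systolic_bp, lower: 91, upper: 100, points: 2}
  - {component: systolic_bp, lower: 101, upper: 110, points: 1}
  - {component: systolic_bp, lower: 111, upper: 219, points: 0}
  - {component: systolic_bp, lower: 220, upper: 300, points: 3}
  - {component: heart_rate, lower: 10, upper: 40, points: 3}
  - {component: heart_rate, lower: 41, upper: 50, points: 1}
  - {component: heart_rate, lower: 51, upper: 90, points: 0}
  - {component: heart_rate, lower: 91, upper: 110, points: 1}
  - {component: heart_rate, lower: 111, upper: 130, points: 2}
  - {component: heart_rate, lower: 131, upper: 300, points: 3}
avpu: {A: 0, V: 3, P: 3, U: 3}
supplemental_o2: {true: 2, false: 0}
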