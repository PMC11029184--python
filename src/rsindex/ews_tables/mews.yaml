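# Modified Early Warning Score (Subbe et al., QJM 2001).
# MEWS does not score oxygen saturation or supplemental oxygen.
system: MEWS
source: Subbe et al. 2001 MEWS chart
bands:
  - {component: systolic_bp, lower: 30, upper: 70, points: 3}
  - {component: systolic_bp, lower: 71, upper: 80, points: 2}
  - {component: systolic_bp, lower: 81, upper: 100, points: 1}
  - {component: systolic_bp, lower: 101, upper: 199, points: 0}
  - {component: systolic_bp, lower: 200, upper: 300, points: 2}
  - {component: heart_rate, lower: 10, upper: 40, points: 2}
  - {component: heart_rate, lower: 41, upper: 50, points: 1}
  - {component: heart_rate, lower: 51, upper: 100, points: 0}
  - {component: heart_rate, lower: 101, upper: 110, points: 1}
  - {component: heart_rate, lower: 111, upper: 129, points: 2}
  - {component: heart_rate, lower: 130, upper: 300, points: 3}
  - {component: resp_rate, lower: 0, upper: 8, points: 2}
  - {component: resp_rate, lower: 9, upper: 14, points: 0}
  - {component: resp_rate, lower: 15, upper: 20, points: 1}
  - {component: resp_rate, lower: 21, upper: 29, points: 2}
  - {component: resp_rate, lower: 30, upper: 80, points: 3}
  - {component: temperature, lower: 30.0, upper: 34.9, points: 2}
  - {component: temperature, lower: 35.0, upper: 38.4, points: 0}
  - {component: temperature, lower: 38.5, upper: 43.0, points: 2}
avpu: {A: 0, V: 1, P: 2, U: 3}
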