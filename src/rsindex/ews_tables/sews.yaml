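# Standardised Early Warning Score (Paterson et al., Clin Med 2006).
# Transcription of the published SEWS chart; bands are user-replaceable.
system: SEWS
source: Paterson et al. 2006 SEWS chart (transcription)
bands:
  - {component: resp_rate, lower: 0, upper: 8, points: 2}
  - {component: resp_rate, lower: 9, upper: 20, points: 0}
  - {component: resp_rate, lower: 21, upper: 30, points: 1}
  - {component: resp_rate, lower: 31, upper: 35, points: 2}
  - {component: resp_rate, lower: 36, upper: 80, points: 3}
  - {component: spo2, lower: 50, upper: 84, points: 3}
  - {component: spo2, lower: 85, upper: 89, points: 2}
  - {component: spo2, lower: 90, upper: 92, points: 1}
  - {component: spo2, lower: 93, upper: 100, points: 0}
  - {component: temperature, lower: 30.0, upper: 33.9, points: 3}
  - {component: temperature, lower: 34.0, upper: 34.9, points: 2}
  - {component: temperature, lower: 35.0, upper: 35.9, points: 1}
  - {component: temperature, lower: 36.0, upper: 37.9, points: 0}
  - {component: temperature, lower: 38.0, upper: 38.9, points: 1}
  - {component: temperature, lower: 39.0, upper: 43.0, points: 2}
  - {component: systolic_bp, lower: 30, upper: 69, points: 3}
  - {component: systolic_bp, lower: 70, upper: 79, points: 2}
  - {component: systolic_bp, lower: 80, upper: 99, points: 1}
  - {component: systolic_bp, lower: 100, upper: 199, points: 0}
  - {component: systolic_bp, lower: 200, upper: 300, points: 3}
  - {component: heart_rate, lower: 10, upper: 29, points: 3}
  - {component: heart_rate, lower: 30, upper: 39, points: 2}
  - {component: heart_rate, lower: 40, upper: 49, points: 1}
  - {component: heart_rate, lower: 50, upper: 99, points: 0}
  - {component: heart_rate, lower: 100, upper: 109, points: 1}
  - {component: heart_rate, lower: 110, upper: 129, points: 2}
  - {component: heart_rate, lower: 130, upper: 300, points: 3}
avpu: {A: 0, V: 1, P: 2, U: 3}
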