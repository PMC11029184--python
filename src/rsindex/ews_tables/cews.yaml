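# Centile-based Early Warning Score (Tarassenko et al., Resuscitation 2011).
# Cut-offs follow the centile scheme of the published chart (3 points
# beyond the 1st/99th centiles of the hospital vital-sign distributions,
# 2 for 1st-5th / 95th-99th, 1 for 5th-10th / 90th-95th, 0 inside the
# 10th-90th band).  Approximate transcription; bands are user-replaceable.
system: CEWS
source: Tarassenko et al. 2011 centile-based chart (transcription)
bands:
  - {component: heart_rate, lower: 10, upper: 44, points: 3}
  - {component: heart_rate, lower: 45, upper: 50, points: 2}
  - {component: heart_rate, lower: 51, upper: 54, points: 1}
  - {component: heart_rate, lower: 55, upper: 100, points: 0}
  - {component: heart_rate, lower: 101, upper: 109, points: 1}
  - {component: heart_rate, lower: 110, upper: 126, points: 2}
  - {component: heart_rate, lower: 127, upper: 300, points: 3}
  - {component: systolic_bp, lower: 30, upper: 84, points: 3}
  - {component: systolic_bp, lower: 85, upper: 95, points: 2}
  - {component: systolic_bp, lower: 96, upper: 100, points: 1}
  - {component: systolic_bp, lower: 101, upper: 151, points: 0}
  - {component: systolic_bp, lower: 152, upper: 159, points: 1}
  - {component: systolic_bp, lower: 160, upper: 178, points: 2}
  - {component: systolic_bp, lower: 179, upper: 300, points: 3}
  - {component: resp_rate, lower: 0, upper: 6, points: 3}
  - {component: resp_rate, lower: 7, upper: 10, points: 2}
  - {component: resp_rate, lower: 11, upper: 13, points: 1}
  - {component: resp_rate, lower: 14, upper: 25, points: 0}
  - {component: resp_rate, lower: 26, upper: 28, points: 1}
  - {component: resp_rate, lower: 29, upper: 33, points: 2}
  - {component: resp_rate, lower: 34, upper: 80, points: 3}
  - {component: temperature, lower: 30.0, upper: 35.4, points: 3}
  - {component: temperature, lower: 35.5, upper: 35.9, points: 2}
  - {component: temperature, lower: 36.0, upper: 36.2, points: 1}
  - {component: temperature, lower: 36.3, upper: 37.3, points: 0}
  - {component: temperature, lower: 37.4, upper: 37.6, points: 1}
  - {component: temperature, lower: 37.7, upper: 38.1, points: 2}
  - {component: temperature, lower: 38.2, upper: 43.0, points: 3}
  - {component: spo2, lower: 50, upper: 84, points: 3}
  - {component: spo2, lower: 85, upper: 90, points: 2}
  - {component: spo2, lower: 91, upper: 93, points: 1}
  - {component: spo2, lower: 94, upper: 100, points: 0}
avpu: {A: 0, V: 1, P: 2, U: 3}
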