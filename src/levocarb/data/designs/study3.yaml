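# Multiple-dose study in healthy volunteers used for external evaluation:
# 75/18.75 mg LD/CD morning dose, then five 45/11.25 mg doses every 2.4 h.
# Samples 5 min before each dose and 20, 40, 60, 90 min after each intake.
label: study3
n_subjects: 10
pre_dose_positive: false
dosing:
  times: [0.0, 144.0, 288.0, 432.0, 576.0, 720.0]
  ld_amounts: [75.0, 45.0, 45.0, 45.0, 45.0, 45.0]
  cd_ratio: 4.0
sampling_times: [-5, 20, 40, 60, 90, 139, 164, 184, 204, 234, 283, 308,
                 328, 348, 378, 427, 452, 472, 492, 522, 571, 596, 616,
                 636, 666, 715, 740, 760, 780, 810]
lod:
  levodopa: 0.0005    # µg/mL; calibrated once so ~5.6% of study-1+2 samples censor
  carbidopa: 0.0002
covariates:
  wt:  {mean: 71.3, sd: 13.7, min: 52.0, max: 100.0}
  age: {mean: 24.7, sd: 4.3, min: 20.0, max: 32.0}
  sex: {p_female: 0.6}
  hy:  {value: 0}
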