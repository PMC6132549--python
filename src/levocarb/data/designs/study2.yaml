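# Single-dose study in patients with advanced Parkinson's disease:
# 150% of the individual levodopa-equivalent morning dose (110/27.5 to
# 410/102.5 mg LD/CD), sampling to 6 h, detectable pre-dose concentrations
# after overnight washout.
label: study2
n_subjects: 18
pre_dose_positive: true
dosing:
  times: [0.0]
  individualized:
    ld_range: [110.0, 410.0]
    round_to: 5.0        # microtablet strength, mg levodopa
  cd_ratio: 4.0
sampling_times: [-30, 0, 15, 30, 45, 60, 80, 100, 120, 150, 180, 210,
                 240, 300, 360]
lod:
  levodopa: 0.0005    # µg/mL; calibrated once so ~5.6% of study-1+2 samples censor
  carbidopa: 0.0002
covariates:
  wt:  {mean: 75.4, sd: 11.0, min: 55.0, max: 96.0}
  age: {mean: 71.4, sd: 6.3, min: 61.0, max: 82.0}
  sex: {p_female: 0.2778}          # 5 of 18
  hy:  {mean: 3.2, sd: 0.9, min: 2, max: 5, integer: true}
  years_ld:    {mean: 9.5, sd: 6.7, min: 2.0, max: 33.0}
  t_diagnosis: {mean: 9.6, sd: 6.7, min: 2.0, max: 33.0}
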