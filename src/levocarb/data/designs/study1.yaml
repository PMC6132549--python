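# Single-dose study in healthy volunteers: 100/25 mg LD/CD dissolved
# microtablets, dense sampling to 24 h.  One pre-dose sample, then every
# 10 min during the first hour, every 20 min to 2 h, half-hourly to 3 h,
# hourly to 6 h, and at 8, 10, 12 and 24 h.
label: study1
n_subjects: 18
pre_dose_positive: false
dosing:
  times: [0.0]
  ld_amounts: [100.0]
  cd_ratio: 4.0        # LD:CD ratio of the microtablet
sampling_times: [-30, 10, 20, 30, 40, 50, 60, 80, 100, 120, 150, 180,
                 240, 300, 360, 480, 600, 720, 1440]
lod:
  levodopa: 0.0005    # µg/mL; calibrated once so ~5.6% of study-1+2 samples censor
  carbidopa: 0.0002
covariates:
  wt:  {mean: 71.7, sd: 11.3, min: 59.0, max: 95.0}
  age: {mean: 26.0, sd: 6.2, min: 19.0, max: 46.0}
  sex: {p_female: 0.5}
  hy:  {value: 0}
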