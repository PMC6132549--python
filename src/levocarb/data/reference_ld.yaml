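# Final levodopa population PK model (joint LD/CD analysis).
# Two-compartment disposition, parallel transit chains (5, 6).
# Typical clearance is per milligram carbidopa for a subject with 0 mg
# carbidopa and Hoehn & Yahr at its pooled mean (1.53); bodyweight enters
# all disposition parameters allometrically (exponents fixed).
# IIV sd values are on the standard-deviation scale of each random effect
# (multiplicative for lognormal, logit-scale for fa1).
drug: levodopa
n_disposition_compartments: 2
transit: {n1: 5, n2: 6}
theta:
  cl_f: 1.31      # L/min, 70 kg, 0 mg CD, HY 1.53
  vc_f: 45.4      # L
  q_f: 0.667      # L/min
  vp_f: 44.9      # L
  mtt1: 16.1      # min
  mtt2: 86.2      # min
  fa1: 0.749
  f_rel: 1.0      # fixed
  c0: 0.120       # µg/mL pre-dose concentration
fixed: [f_rel]
covariate_effects:
  - {parameter: cl_f, covariate: wt, kind: allometric, coefficient: 0.75, reference: 70.0}
  - {parameter: q_f, covariate: wt, kind: allometric, coefficient: 0.75, reference: 70.0}
  - {parameter: vc_f, covariate: wt, kind: allometric, coefficient: 1.0, reference: 70.0}
  - {parameter: vp_f, covariate: wt, kind: allometric, coefficient: 1.0, reference: 70.0}
  - {parameter: cl_f, covariate: hy, kind: linear, coefficient: -0.0616, reference: 1.53}
  - {parameter: f_rel, covariate: age, kind: linear, coefficient: 0.00172, reference: 48.7}
  - {parameter: cl_f, covariate: cd_dose, kind: interaction, coefficient: 86.7, reference: 0.0}
omega:
  cl_f: {sd: 0.150, dist: lognormal}
  vc_f: {sd: 0.395, dist: lognormal}
  mtt1: {sd: 0.345, dist: lognormal}
  mtt2: {sd: 0.152, dist: lognormal}
  fa1: {sd: 0.996, dist: logitnormal}
  f_rel: {sd: 0.283, dist: lognormal}
  c0: {sd: 1.80, dist: lognormal}
sigma:
  prop_healthy: 0.150
  prop_patient: 0.0702
  add_healthy: 0.00406   # µg/mL
  add_patient: 0.0       # estimated low, fixed to zero
  shared_fraction: 0.285
variants:
  # column with unfixed parameter-covariate coefficients
  # (low-influence relations removed)
  reestimated:
    theta:
      cl_f: 1.21
      vc_f: 45.5
      q_f: 0.661
      vp_f: 45.1
      mtt1: 16.1
      mtt2: 86.5
      fa1: 0.747
      c0: 0.120
    covariate_effects:
      - {parameter: cl_f, covariate: wt, kind: allometric, coefficient: 0.75, reference: 70.0}
      - {parameter: q_f, covariate: wt, kind: allometric, coefficient: 0.75, reference: 70.0}
      - {parameter: vc_f, covariate: wt, kind: allometric, coefficient: 1.0, reference: 70.0}
      - {parameter: vp_f, covariate: wt, kind: allometric, coefficient: 1.0, reference: 70.0}
      - {parameter: cl_f, covariate: hy, kind: linear, coefficient: -0.0967, reference: 1.53}
      - {parameter: cl_f, covariate: cd_dose, kind: interaction, coefficient: 119.1, reference: 0.0}
    omega:
      cl_f: {sd: 0.146, dist: lognormal}
      vc_f: {sd: 0.389, dist: lognormal}
      mtt1: {sd: 0.344, dist: lognormal}
      mtt2: {sd: 0.153, dist: lognormal}
      fa1: {sd: 0.991, dist: logitnormal}
      f_rel: {sd: 0.288, dist: lognormal}
      c0: {sd: 1.80, dist: lognormal}
    sigma:
      prop_healthy: 0.150
      prop_patient: 0.0703
      add_healthy: 0.00407
      add_patient: 0.0
      shared_fraction: 0.285
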