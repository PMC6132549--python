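# Final carbidopa population PK model (joint LD/CD analysis).
# One-compartment disposition, parallel transit chains (3, 10).
drug: carbidopa
n_disposition_compartments: 1
transit: {n1: 3, n2: 10}
theta:
  cl_f: 1.05      # L/min, 70 kg, age 48.7, HY 1.53
  vc_f: 168.0     # L
  mtt1: 34.6      # min
  mtt2: 121.0     # min
  fa1: 0.570
  f_rel: 1.0      # fixed
  c0: 0.0256      # µg/mL pre-dose concentration
fixed: [f_rel]
covariate_effects:
  - {parameter: cl_f, covariate: wt, kind: allometric, coefficient: 0.75, reference: 70.0}
  - {parameter: vc_f, covariate: wt, kind: allometric, coefficient: 1.0, reference: 70.0}
  - {parameter: cl_f, covariate: age, kind: linear, coefficient: -0.0119, reference: 48.7}
  - {parameter: cl_f, covariate: hy, kind: linear, coefficient: 0.0141, reference: 1.53}
  - {parameter: mtt2, covariate: sex, kind: linear, coefficient: 0.178, reference: 0.389}
omega:
  cl_f: {sd: 0.209, dist: lognormal}
  mtt1: {sd: 0.319, dist: lognormal}
  mtt2: {sd: 0.272, dist: lognormal}
  fa1: {sd: 0.812, dist: logitnormal}
  f_rel: {sd: 0.481, dist: lognormal}
  c0: {sd: 0.896, dist: lognormal}
sigma:
  prop_healthy: 0.0770
  prop_patient: 0.0386
  add_healthy: 0.00415   # µg/mL
  add_patient: 0.00684
  shared_fraction: 0.285
variants:
  reestimated:
    theta:
      cl_f: 1.05
      vc_f: 168.0
      mtt1: 34.6
      mtt2: 120.0
      fa1: 0.570
      c0: 0.0255
    covariate_effects:
      - {parameter: cl_f, covariate: wt, kind: allometric, coefficient: 0.75, reference: 70.0}
      - {parameter: vc_f, covariate: wt, kind: allometric, coefficient: 1.0, reference: 70.0}
      - {parameter: cl_f, covariate: age, kind: linear, coefficient: -0.0114, reference: 48.7}
    omega:
      cl_f: {sd: 0.210, dist: lognormal}
      mtt1: {sd: 0.321, dist: lognormal}
      mtt2: {sd: 0.292, dist: lognormal}
      fa1: {sd: 0.805, dist: logitnormal}
      f_rel: {sd: 0.484, dist: lognormal}
      c0: {sd: 0.901, dist: lognormal}
    sigma:
      prop_healthy: 0.0766
      prop_patient: 0.0389
      add_healthy: 0.00415
      add_patient: 0.00677
      shared_fraction: 0.285
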