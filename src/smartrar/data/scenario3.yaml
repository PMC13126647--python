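name: "scenario3"
description: "antagonism: best stage-1 option is not in the optimal regime"
p1:
  0: 0.30
  1: 0.40
p2:
  "0,0": 0.60
  "0,1": 0.50
  "0,2": 0.30
  "1,0": 0.18
  "1,1": 0.15
  "1,2": 0.10
p3: 0.15
lambda_sens: 0.53
lambda_spec: 0.90
n_patients: 200
t_enroll: 130
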