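name: "scenario2"
description: "purely delayed effects; equal stage-1 pCR probabilities"
p1:
  0: 0.30
  1: 0.30
p2:
  "0,0": 0.40
  "0,1": 0.30
  "0,2": 0.15
  "1,0": 0.40
  "1,1": 0.60
  "1,2": 0.25
p3: 0.15
lambda_sens: 0.53
lambda_spec: 0.90
n_patients: 200
t_enroll: 130
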