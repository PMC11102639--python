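design:
  name: actor_patient
  assignment: within_subject
  conditions:
  - control
  - early_dss
  cases_per_condition:
    control:
    - a01
    - a02
    - a03
    - a04
    - a05
    - a06
    early_dss:
    - a07
    - a08
    - a09
    - a10
    - a11
    - a12
  confidence_scale:
  - 1
  - 10
n_gps: 30
easiness:
  a01: -1.0964455041630647
  a02: -0.6964455041630648
  a03: -0.2964455041630648
  a04: 0.10355449583693535
  a05: 0.5035544958369352
  a06: 0.9035544958369351
  a07: -1.0964455041630647
  a08: -0.6964455041630648
  a09: -0.2964455041630648
  a10: 0.10355449583693535
  a11: 0.5035544958369352
  a12: 0.9035544958369351
sigma_g: 0.6
delta_cond:
  control: 0.0
  early_dss: 0.42618155685979586
correct_labels:
  a01: acute coronary syndrome
  a02: pulmonary embolism
  a03: appendicitis
  a04: heart failure
  a05: diverticulitis
  a06: aortic dissection
  a07: ectopic pregnancy
  a08: copd
  a09: anaemia
  a10: pericarditis
  a11: pyelonephritis
  a12: asthma
wrong_labels:
  a01:
    gerd: 0.6
    musculoskeletal pain: 0.25
    panic attack: 0.15
  a02:
    pneumonia: 0.4
    pleurisy: 0.35
    panic attack: 0.25
  a03:
    gastroenteritis: 0.6
    urinary tract infection: 0.25
    constipation: 0.15
  a04:
    copd: 0.4
    asthma: 0.35
    pneumonia: 0.25
  a05:
    irritable bowel syndrome: 0.6
    gastroenteritis: 0.25
    constipation: 0.15
  a06:
    acute coronary syndrome: 0.4
    musculoskeletal pain: 0.35
    gerd: 0.25
  a07:
    appendicitis: 0.6
    ovarian cyst: 0.25
    pelvic inflammatory disease: 0.15
  a08:
    asthma: 0.4
    heart failure: 0.35
    bronchitis: 0.25
  a09:
    hypothyroidism: 0.6
    heart failure: 0.25
    depression: 0.15
  a10:
    acute coronary syndrome: 0.4
    musculoskeletal pain: 0.35
    pleurisy: 0.25
  a11:
    urinary tract infection: 0.6
    appendicitis: 0.25
    renal colic: 0.15
  a12:
    copd: 0.4
    bronchitis: 0.35
    panic attack: 0.25
conf_mean: 7.5
conf_sd: 1.6
conf_shift: 0.0
seniority_bands:
- - 0
  - 10
  - 0.567
- - 11
  - 20
  - 0.166
- - 21
  - 40
  - 0.267
gamma: -0.03
seed: 202407
wrong_labels_by_condition: {}
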