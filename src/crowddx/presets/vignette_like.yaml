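design:
  name: vignette
  assignment: between_subject
  conditions:
  - control
  - early_dss
  - late_dss
  cases_per_condition:
    control:
    - v1
    - v2
    - v3
    - v4
    - v5
    - v6
    - v7
    - v8
    - v9
    early_dss:
    - v1
    - v2
    - v3
    - v4
    - v5
    - v6
    - v7
    - v8
    - v9
    late_dss:
    - v1
    - v2
    - v3
    - v4
    - v5
    - v6
    - v7
    - v8
    - v9
  confidence_scale:
  - 1
  - 8
n_gps: 87
easiness:
  v1: -0.48362797812655
  v2: -0.20862797812654998
  v3: 0.06637202187345004
  v4: 0.34137202187345006
  v5: 0.6163720218734501
  v6: 0.89137202187345
  v7: 1.1663720218734501
  v8: 1.4413720218734503
  v9: 1.7163720218734502
sigma_g: 0.6
delta_cond:
  control: 0.0
  early_dss: 0.3290369992447958
  late_dss: 0.16803720875567585
correct_labels:
  v1: acute coronary syndrome
  v2: pulmonary embolism
  v3: aortic dissection
  v4: appendicitis
  v5: ectopic pregnancy
  v6: diverticulitis
  v7: heart failure
  v8: copd
  v9: anaemia
wrong_labels:
  v1:
    stable angina: 0.3
    gerd: 0.25
    musculoskeletal pain: 0.2
    panic attack: 0.15
    pericarditis: 0.1
  v2:
    pneumonia: 0.3
    pleurisy: 0.25
    panic attack: 0.2
    musculoskeletal pain: 0.15
    bronchitis: 0.1
  v3:
    acute coronary syndrome: 0.3
    gerd: 0.25
    musculoskeletal pain: 0.2
    pericarditis: 0.15
    pleurisy: 0.1
  v4:
    gastroenteritis: 0.3
    mesenteric adenitis: 0.25
    urinary tract infection: 0.2
    constipation: 0.15
    ovarian cyst: 0.1
  v5:
    appendicitis: 0.3
    ovarian cyst: 0.25
    urinary tract infection: 0.2
    pelvic inflammatory disease: 0.15
    miscarriage: 0.1
  v6:
    irritable bowel syndrome: 0.3
    constipation: 0.25
    gastroenteritis: 0.2
    colorectal cancer: 0.15
    urinary tract infection: 0.1
  v7:
    copd: 0.3
    asthma: 0.25
    pneumonia: 0.2
    anaemia: 0.15
    obesity-related dyspnoea: 0.1
  v8:
    asthma: 0.3
    heart failure: 0.25
    bronchitis: 0.2
    pneumonia: 0.15
    lung cancer: 0.1
  v9:
    heart failure: 0.3
    hypothyroidism: 0.25
    copd: 0.2
    depression: 0.15
    chronic fatigue: 0.1
conf_mean: 5.8
conf_sd: 1.4
conf_shift: 0.6
seniority_bands:
- - 0
  - 10
  - 0.646
- - 11
  - 20
  - 0.181
- - 21
  - 40
  - 0.173
gamma: -0.01
seed: 202406
wrong_labels_by_condition: {}
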