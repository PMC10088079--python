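pk:
  dapagliflozin:
    CL: 19.5
    Vc: 82.0
    CLD: 10.3
    VT: 122.0
    Kt: 6.5
    n_transit: 2
    fed_effect: 0.254
    iiv:
      CL: 0.025
      Vc: 0.0944
      VT: 0.0583
      Kt: 0.23
    sigma2_prop: 0.457
    sigma2_add: 0.462
  canagliflozin:
    CL: 12.0
    Vc: 85.5
    CLD: 9.77
    VT: 108.0
    Kt: 6.38
    n_transit: 4
    fed_effect: null
    iiv:
      CL: 0.059
      Vc: 0.0243
      CLD: 0.128
      VT: 0.0314
      Kt: 0.0317
    sigma2_prop: 0.126
    sigma2_add: 0.0
  empagliflozin:
    CL: 4.25
    Vc: 30.6
    CLD: 1.37
    VT: 28.3
    Kt: 4.13
    n_transit: 2
    fed_effect: null
    iiv:
      CL: 0.0569
      Vc: 0.0563
      VT: 0.22
      Kt: 0.0567
    sigma2_prop: 0.521
    sigma2_add: 0.0
biomarker:
  Emax: 0.606
  EC50_by_drug:
    dapagliflozin: 56.6
    canagliflozin: 2310.0
    empagliflozin: 841.0
  sigma2_prop: 0.222
  sigma2_add: 0.0646
  iiv: {}
endpoints:
  fpg_baseline_pop: 160.0
  p_fmax:
    naive: 1.45
    non_naive: 1.9
    add_on: -1.37
    mixed: 4.3
  k_fp: 0.34
  dis_fp: 3.13
  slope_fd: -43.3
  hba1c_baseline_pop: 7.92
  p_hmax:
    naive: -0.2
    non_naive: 0.051
    add_on: -0.23
    mixed: -0.06
  k_hp: 0.24
  dis_hp: 0.31
  k_out: 0.2
  k_in2: 0.5
  iiv:
    fpg_baseline: 0.054
    p_fmax:
      naive: 5.74
      non_naive: 0.0
      add_on: 6.83
      mixed: 0.87
    k_fp: 0.427
    dis_fp: 0.0
    slope_fd: 0.292
    hba1c_baseline: 0.039
    p_hmax:
      naive: 0.08
      non_naive: 0.0
      add_on: 0.13
      mixed: 0.2
    k_hp: 0.294
    dis_hp: 1.367
    k_out: 0.164
    k_in2: 0.0
  sigma2_fpg: 0.033
  sigma2_hba1c: 0.006
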