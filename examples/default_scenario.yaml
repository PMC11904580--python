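active:
  pfs_rate: 0.2222222222222222
  rel_rate: 0.25641025641025644
  tox_frac_concentration: 5.0
  tox_frac_mean: 0.1111111111111111
ae_fragmentation: 2
background_ae_rate: 1.0
control:
  pfs_rate: 0.47619047619047616
  rel_rate: 0.22727272727272727
  tox_frac_concentration: 5.0
  tox_frac_mean: 0.09523809523809523
cutoff_month: null
n_active: 461
n_control: 230
serious_prob: 0.6
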