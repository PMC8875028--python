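{
  "asphericity_mean": 0.14437345287756448,
  "complete": true,
  "eps_vp": 2.0,
  "kappa": 10.0,
  "r_ee_mean": 4.561452253254603,
  "r_ee_se": 0.15599220735518493,
  "shape_label": "double",
  "trough_count": 2,
  "u_vl_mean": -210.00135286165255,
  "u_vl_se": 0.8463038048205759
}
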