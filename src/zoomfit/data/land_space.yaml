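# Sampling ranges for the length-dependence parameters of the Land et al.
# mouse contraction model (identifiability analysis).  T_ref in kPa,
# Ca50ref in uM, rates in 1/ms.
parameters:
- {name: T_ref,   min: 100.0, max: 140.0}
- {name: Ca50ref, min: 0.5,   max: 0.8}
- {name: TRPN50,  min: 0.25,  max: 0.5}
- {name: n_TRPN,  min: 1.0,   max: 2.5}
- {name: k_TRPN,  min: 0.0,   max: 0.5}
- {name: n_xb,    min: 3.0,   max: 7.0}
- {name: k_xb,    min: 0.0,   max: 0.6}
- {name: beta1,   min: -2.0,  max: -1.0}
- {name: beta0,   min: 1.0,   max: 5.0}
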