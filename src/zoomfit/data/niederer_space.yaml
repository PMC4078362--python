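# Initial sampling ranges and a-priori hard constraints for the varied
# parameters of the Niederer et al. cardiac contraction model (rat model
# re-fitted to mouse behaviour at 37 C).  Units as in the model code:
# Ca50ref in mM, rates in 1/ms except k_on in 1/(uM*s), T_ref in kPa.
parameters:
- {name: Ca50ref,  min: 0.0003, max: 0.0008}
- {name: k_refoff, min: 0.0,    max: 0.80,  hard_min: 0.05, hard_max: 0.4}
- {name: k_on,     min: 0.0,    max: 400.0, hard_min: 50.0, hard_max: 300.0}
- {name: n_r,      min: 2.0,    max: 4.0,   hard_min: 1.0}
- {name: beta0,    min: 1.0,    max: 5.0,   hard_max: 6.0}
- {name: beta1,    min: -8.0,   max: 0.0}
- {name: gamma,    min: 2.0,    max: 100.0, hard_min: 1.0,  hard_max: 5.0}
- {name: nH,       min: 4.0,    max: 9.0,   hard_min: 1.0,  hard_max: 15.0}
- {name: T_ref,    min: 100.0,  max: 140.0, hard_min: 90.0, hard_max: 140.0}
- {name: alpha_0,  min: 0.0,    max: 0.048}
- {name: alpha_r1, min: 0.0,    max: 0.012}
- {name: alpha_r2, min: 0.0,    max: 0.0105}
- {name: K_z,      min: 0.1,    max: 0.2}
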