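parameter,set1,set2,set3,set4
Ca50ref,3.51e-04,3.45e-04,3.45e-04,3.71e-04
k_refoff,0.11,0.12,0.08,0.14
k_on,231.4,268.2,240.2,294.0
beta0,0.66,0.28,0.92,0.71
beta1,-1.33,-1.34,-1.24,-1.47
gamma,3.73,4.56,4.61,4.29
nH,11.31,12.50,14.22,11.70
T_ref,128.3,126.2,113.4,104.1
alpha_0,0.03,0.02,0.04,0.05
alpha_r1,0.31,0.28,0.38,0.35
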