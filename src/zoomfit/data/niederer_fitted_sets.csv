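parameter,set1,set2,set3
Ca50ref,0.31e-3,0.33e-3,0.35e-3
k_refoff,0.08,0.12,0.08
k_on,227.2,163.1,186.7
n_r,1.38,1.66,2.02
beta0,0.10,0.06,0.07
beta1,-1.35,-1.14,-1.29
gamma,3.99,4.75,4.79
nH,13.48,10.23,12.09
T_ref,135.8,130.6,115.8
alpha_0,0.03,0.03,0.06
alpha_r1,0.48,0.46,0.43
alpha_r2,0.009,0.016,0.010
K_z,0.07,0.10,0.07
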