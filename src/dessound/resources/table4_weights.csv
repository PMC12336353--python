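neuron,w_Vc,w_omega,w_MW,w_T,w_out
1,-2.24536,-0.48558,1.098708,-1.16422,0.630794
2,0.944691,-2.52083,-0.67325,0.373787,0.758028
3,-1.01834,-1.29702,1.427834,-1.75557,0.977823
4,-1.74537,1.232633,1.03008,-1.4877,-0.99896
5,1.276081,-0.35078,-1.66558,-1.82055,0.730877
6,-1.16913,1.762558,1.645331,0.812039,0.225133
7,-0.31927,-0.60319,2.715422,-0.02673,0.97998
8,1.163699,1.667596,0.089376,-1.92274,0.055369
9,-0.93382,-0.68464,2.549148,-0.03313,-0.04095
10,1.244022,1.623924,0.463342,-1.85488,0.602695
11,-0.47005,1.138715,-1.54125,-1.98668,-0.54431
12,1.003801,-0.67099,-1.64259,1.919385,-0.00381
13,1.557248,-2.16729,-0.7101,0.462178,0.801705
14,-0.27949,1.406818,1.204804,2.081152,0.149322
15,-1.77034,1.655671,1.199766,0.724712,0.690356
16,-1.22579,-1.24965,2.101388,0.599993,0.477281
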