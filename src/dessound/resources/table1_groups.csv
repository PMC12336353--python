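group_id,tb_k,tc_k,pc_k,vc_k,n_atoms
CH3,23.58,0.0141,-0.0012,65,4
CH2,22.288,0.0189,0.0000,56,3
>CH-,21.74,0.0164,0.0020,41,2
>C<,18.25,0.0067,0.0043,27,1
=CH2,18.18,0.0113,-0.0028,56,3
=CH-,24.96,0.0129,-0.0006,46,2
=C<,24.14,0.0117,0.0011,38,1
-O-,22.42,0.0168,0.0015,18,1
>C=O,94.97,0.0284,0.0028,55,2
N+,11.74,0.0169,0.0074,9,1
-CN,125.66,0.0496,-0.0101,91,2
F-,-0.03,0.0111,-0.0057,27,1
Cl-,38.13,0.0105,-0.0049,58,1
Br-,66.86,0.0133,0.0057,71,1
I-,93.84,0.0068,-0.0034,97,1
OH,92.88,0.0741,0.0112,28,2
CH2_ring,27.15,0.0100,0.0025,48,3
>CH-_ring,21.78,0.0122,0.0004,38,2
>C<_ring,21.32,0.0042,0.0061,27,1
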