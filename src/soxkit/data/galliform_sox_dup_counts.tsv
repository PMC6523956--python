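species	singleton	dispersed	proximal	tandem	wgd_segmental
C_japonica	0	13	0	4	1
G_gallus	0	12	1	3	2
C_virginianus	0	13	1	0	0
C_squamata	0	14	0	0	0
N_meleagris	0	9	1	5	0
B_thoracicus	0	13	0	0	0
M_gallopavo	0	9	0	4	0
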