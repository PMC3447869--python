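locus,finland_ar,finland_he,oklahoma_ar,oklahoma_he
Cervid1,6,0.719,14,0.847
INRA011,4,0.646,5,0.667
N,7,0.805,13,0.876
Q,7,0.777,15,0.861
ETH152,6,0.796,8,0.800
BM203,8,0.799,12,0.742
K,2,0.497,3,0.452
BL25,4,0.484,4,0.593
BM6438,4,0.678,9,0.790
O,3,0.543,4,0.509
BM848,6,0.748,10,0.829
BM6506,5,0.677,9,0.787
D,7,0.720,9,0.824
OarFCB193,6,0.797,12,0.809
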