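id,set,exp_dg,is_reference,non_binder
80,1,-32.6,0,0
81,1,-38.2,0,0
82,1,-28.2,0,0
83,1,-27.5,0,0
84,1,-29.9,0,0
ref,1,,1,0
100,2,-24.6,0,0
101,2,-38.3,0,0
105,2,-39.5,0,0
106,2,-40.3,0,0
10,3,-30.3,0,0
11,3,-38.1,0,0
15,3,-29.5,0,0
19,3,-29.6,0,0
21,3,-38.3,0,0
23,3,-31.5,0,0
26,3,-43.9,0,0
28,3,-37.4,0,0
34,3,-29.7,0,0
61,3,-24.6,0,1
ref1,3,,1,0
ref2,3,,1,0
ref3,3,,1,0
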