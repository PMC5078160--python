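ligand,set,structure,exp_dg,non_binder,gscore,emodel,ifdscore,mmgbsa
80,1,3VHA,-32.6,0,-42.6,-326.8,-2079.7,-367.9
81,1,3VHA,-38.2,0,-46.9,-398.1,-2086.9,-379.7
82,1,3VHA,-28.2,0,-47.0,-378.7,-2083.8,-395.5
83,1,3VHA,-27.5,0,-45.4,-375.6,-2085.9,-413.1
84,1,3VHA,-29.9,0,-45.4,-368.3,-2081.5,-405.6
100,2,3VHA,-24.6,0,-41.3,-333.9,-2054.0,-342.8
101,2,3VHA,-38.3,0,-38.7,-289.5,-2047.0,-311.1
105,2,3VHA,-39.5,0,-37.4,-300.7,-2046.5,-319.5
106,2,3VHA,-40.3,0,-37.8,-308.4,-2046.6,-298.7
100,2,2WI7,-24.6,0,-39.7,-282.2,-1973.7,-357.2
101,2,2WI7,-38.3,0,-38.4,-282.9,-1973.4,-310.9
105,2,2WI7,-39.5,0,-40.7,-307.1,-1978.7,-348.0
106,2,2WI7,-40.3,0,-39.5,-309.7,-1974.8,-338.8
10,3,3OW6,-30.3,0,-51.5,-444.6,-1980.7,-292.2
11,3,3OW6,-38.1,0,-46.9,-401.6,-1977.9,-307.1
15,3,3OW6,-29.5,0,-54.1,-512.3,-1988.8,-347.7
19,3,3OW6,-29.6,0,-47.8,-444.2,-1980.4,-306.3
21,3,3OW6,-38.3,0,-54.2,-493.0,-1989.1,-395.8
23,3,3OW6,-31.5,0,-50.3,-468.3,-1985.9,-333.7
26,3,3OW6,-43.9,0,-53.7,-458.7,-1987.1,-383.3
28,3,3OW6,-37.4,0,-54.4,-457.6,-1986.9,-316.1
34,3,3OW6,-29.7,0,-51.4,-447.2,-1991.3,-305.0
61,3,3OW6,-24.6,1,-50.2,-415.5,-1981.7,-271.4
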