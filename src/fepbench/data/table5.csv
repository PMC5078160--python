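ligand,set,e_qmmm,e_qm_ptch,bq_ptch,bq_cosmo,disp,bsc,g_therm,l_rlx,solv_cosmo,solv_cosmors,dg_bind,dg_prime
80,1,-484.2,-426.7,-156.2,-56.9,-285.5,149.3,93.1,-27.1,-45.9,-54.8,-64.1,-157.2
81,1,-565.5,-491.4,-214.4,-76.2,-324.3,157.4,111.3,-33.8,-55.4,-69.2,-84.3,-195.5
82,1,-487.3,-421.6,-145.2,-45.9,-316.1,145.3,81.4,-21.5,-42.3,-51.5,-104.6,-186.0
83,1,-550.4,-470.1,-218.3,-82.9,-337.8,160.5,99.2,-32.2,-51.3,-60.5,-119.6,-218.8
84,1,-544.9,-471.9,-158.4,-45.0,-340.5,152.6,80.5,-32.7,-57.7,-65.8,-111.6,-192.1
100,2,-487.8,-425.3,-181.7,-65.7,-249.1,148.0,100.1,-16.2,-65.2,-81.9,-33.9,-133.9
101,2,-475.4,-419.0,-164.5,-67.6,-266.1,158.8,61.1,-10.6,-39.3,-48.1,-94.4,-155.5
105,2,-433.5,-379.7,-157.8,-54.3,-238.3,133.1,86.4,-10.2,-49.6,-63.2,-49.3,-135.7
106,2,-438.7,-384.7,-170.7,-70.4,-231.7,130.5,93.7,-10.7,-51.5,-66.1,-52.7,-146.3
10,3,-760.1,-697.2,-447.5,-242.3,-307.2,196.8,123.8,-54.7,-103.8,-141.1,-136.8,-260.6
11,3,-707.8,-645.2,-336.0,-153.8,-324.3,194.7,112.4,-54.8,-89.7,-122.8,-83.0,-195.4
15,3,-851.1,-705.8,-388.7,-182.1,-353.4,256.5,136.8,-48.2,-101.5,-127.4,-68.1,-204.9
19,3,-711.6,-640.0,-386.5,-215.5,-284.3,191.0,106.6,-31.6,-91.4,-123.6,-138.4,-244.9
21,3,-776.1,-684.7,-349.5,-178.5,-359.3,217.3,150.4,-35.9,-92.7,-120.9,-105.9,-256.3
23,3,-748.1,-676.3,-389.8,-185.3,-338.8,186.2,85.8,-47.0,-98.8,-140.3,-163.7,-249.5
26,3,-726.8,-658.0,-349.4,-176.8,-341.0,203.6,116.0,-34.9,-89.9,-123.9,-129.3,-245.3
28,3,-750.0,-685.2,-379.5,-190.6,-325.4,203.3,107.6,-43.9,-95.2,-125.4,-131.0,-238.6
34,3,-749.5,-687.7,-424.5,-235.0,-291.0,196.4,104.5,-52.2,-100.9,-141.0,-132.7,-237.2
61,3,-687.3,-622.1,-282.7,-93.5,-352.0,187.6,123.8,-60.8,-90.3,-121.0,-42.6,-166.5
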