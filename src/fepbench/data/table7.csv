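set,block,from,to,conformer,value,se,selected,exp
1,fes,ref,80,conf1,1.8,0.5,0,
1,fes,ref,80,conf2,-3.6,0.5,1,
1,fes,81,82,conf1,-13.2,0.5,1,10.0
1,fes,81,82,conf2,-16.4,0.5,0,10.0
1,fes,82,ref,conf1,13.3,0.3,0,
1,fes,82,ref,conf2,16.4,0.3,1,
1,fes,83,ref,conf1,3.6,0.5,1,
1,fes,83,ref,conf2,-3.5,0.5,0,
1,fes,84,ref,conf1,8.3,0.5,1,
1,fes,84,ref,conf2,8.3,0.6,0,
2,nowat_2wi7,101,100,conf1,-12.2,0.5,1,13.9
2,nowat_2wi7,101,105,conf1,-7.5,0.2,1,-0.1
2,nowat_2wi7,101,106,conf1,-7.3,0.3,1,2.0
2,nowat_3ft5,101,100,conf1,2.7,0.5,1,13.9
2,nowat_3ft5,101,105,conf1,2.7,0.2,1,-0.1
2,nowat_3ft5,101,106,conf1,3.8,0.3,1,2.0
2,nowat_2wi7_3ft5,101,100,conf1,-12.8,0.5,1,13.9
2,nowat_2wi7_3ft5,101,105,conf1,-8.4,0.2,1,-0.1
2,nowat_2wi7_3ft5,101,106,conf1,-8.7,0.3,1,2.0
2,wat_2wi7,101,100,conf1,11.2,0.9,1,13.9
2,wat_2wi7,101,105,conf1,-6.2,0.4,1,-0.1
2,wat_2wi7,101,106,conf1,-3.7,0.5,1,2.0
2,wat_3ft5,101,100,conf1,18.0,0.9,1,13.9
2,wat_3ft5,101,105,conf1,3.5,0.4,1,-0.1
2,wat_3ft5,101,106,conf1,5.5,0.5,1,2.0
3,fes,10,ref2,conf1,-4.9,0.4,0,
3,fes,10,ref2,conf2,-0.6,0.4,1,
3,fes,11,ref2,conf1,2.3,0.2,1,
3,fes,15,ref3,conf1,4.8,0.5,1,
3,fes,15,ref3,conf2,-4.1,0.6,0,
3,fes,19,ref1,conf1,2.9,0.6,1,
3,fes,21,ref3,conf1,7.3,0.4,1,
3,fes,21,ref3,conf2,-2.1,0.4,0,
3,fes,23,ref2,conf1,-6.7,0.5,1,
3,fes,23,ref2,conf2,-13.1,0.6,0,
3,fes,26,ref2,conf1,3.7,0.4,1,
3,fes,26,ref2,conf2,-12.0,0.4,0,
3,fes,28,ref2,conf1,1.3,0.4,1,
3,fes,28,ref2,conf2,-1.9,0.4,0,
3,fes,34,ref2,conf1,-0.2,0.7,1,
3,fes,34,ref2,conf2,-3.7,0.7,0,
3,fes,61,ref2,S,-4.8,0.8,1,
3,fes,61,ref2,R,-19.8,0.4,0,
3,fes,ref2,ref1,conf1,-11.5,0.6,1,
3,fes,ref3,ref2,conf1,4.5,0.4,1,
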