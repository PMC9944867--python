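name,dose_mg,mw,cmax_uM,fu,ka_per_min,fafg,rb
atazanavir,300,704.90,8.68,0.14,0.1,1.0,1.0
darunavir,600,547.73,10.6,0.05,0.02,1.0,1.0
lopinavir,400,628.80,14.6,0.02,0.02,1.0,1.0
ritonavir,100,720.95,0.930,0.011,0.003,1.0,1.0
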