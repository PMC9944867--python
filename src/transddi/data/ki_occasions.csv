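drug,transporter,occasion_ic50s_uM
atazanavir,BCRP,49.8;30.3;51.5;37.1
atazanavir,OATP1B1,0.583;0.928;0.690
atazanavir,OATP1B3,1.75;2.41;1.43
atazanavir,NTCP,55.9;63.8;77.1
darunavir,BCRP,126;154;148
darunavir,OATP1B1,12.4;7.89;8.29
lopinavir,BCRP,12.7;18.3;15.6
lopinavir,OATP1B1,0.291;0.207;0.162
lopinavir,OATP1B3,5.14;5.04;4.95
lopinavir,NTCP,22.6;18.4;19.9
ritonavir,BCRP,38.6;22.1;17.1;23.6
ritonavir,OATP1B1,0.565;0.574;0.353
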