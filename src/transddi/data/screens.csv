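drug,transporter,tested_conc_uM,mean_percent_control
atazanavir,OAT3,15,100.0
darunavir,OATP1B3,15,100.0
darunavir,NTCP,15,100.0
darunavir,OAT3,10,100.0
lopinavir,OAT3,3,100.0
ritonavir,OATP1B3,0.3,100.0
ritonavir,NTCP,0.3,100.0
ritonavir,OAT3,0.1,100.0
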