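# Rosuvastatin disposition model: transporter pathways with fraction-excreted
# contributions.  Intestinal BCRP is the absorption barrier (fraction
# absorbed 0.5); hepatic uptake totals 0.70 across OATP1B1/OATP1B3/NTCP;
# OAT3 drives active renal secretion.  Clinical AUC ratios are those
# observed on co-administration with each perpetrator.
name: rosuvastatin
pathways:
  - site: intestinal
    transporter: BCRP
    fe: 0.5
  - site: hepatic
    transporter: OATP1B1
    fe: 0.38
  - site: hepatic
    transporter: OATP1B3
    fe: 0.11
  - site: hepatic
    transporter: NTCP
    fe: 0.21
  - site: renal
    transporter: OAT3
    fe: 0.25
clinical_aucr:
  atazanavir: 3.10
  darunavir: 1.48
  lopinavir: 2.10
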