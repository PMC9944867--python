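# Probe-substrate design of each transporter inhibition assay.
# probe_km_uM for BCRP is the measured Michaelis constant of the probe;
# for the uptake assays the probes run at least 10-fold below Km, so the
# stored Km is that documented lower bound (10 x probe concentration) —
# sufficient for the IC50 ~ Ki acceptance condition, conservative for the
# Cheng-Prusoff annotation.
BCRP:
  probe: estrone 3-sulfate
  probe_conc_uM: 1.0
  probe_km_uM: 7.4
  incubation_min: 90
  positive_control: novobiocin
  positive_control_conc_uM: 100
OATP1B1:
  probe: estradiol 17beta-D-glucuronide
  probe_conc_uM: 0.02
  probe_km_uM: 0.2
  incubation_min: 2
  positive_control: rifamycin SV
  positive_control_conc_uM: 100
OATP1B3:
  probe: estradiol 17beta-D-glucuronide
  probe_conc_uM: 0.02
  probe_km_uM: 0.2
  incubation_min: 2
  positive_control: cyclosporin A
  positive_control_conc_uM: 10
NTCP:
  probe: taurocholic acid
  probe_conc_uM: 1.0
  probe_km_uM: 10.0
  incubation_min: 3
  positive_control: pioglitazone
  positive_control_conc_uM: 50
OAT3:
  probe: estrone 3-sulfate
  probe_conc_uM: 1.0
  probe_km_uM: 10.0
  incubation_min: 3
  positive_control: probenecid
  positive_control_conc_uM: 300
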