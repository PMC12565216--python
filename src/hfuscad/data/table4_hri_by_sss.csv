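group,sss_total,n,hri_mean,hri_sd,hri_min,hri_max,inconsistent
WT_SD,0,7,0.69,0.1,0.5,0.8,0
KO_SD,0,4,0.68,0.07,0.6,0.8,0
KO_SD,2,2,0.81,0.14,0.7,0.9,0
KO_SD,3,1,0.77,,0.77,0.77,0
WT_WD,0,4,0.74,0.05,0.7,0.8,0
WT_WD,1,4,0.73,0.07,0.7,0.8,0
WT_WD,2,4,0.91,0.1,0.6,1.1,0
WT_WD,3,3,0.99,0.05,0.9,1.1,0
WT_WD,7,1,1.25,,1.25,1.25,0
KO_WD,1,1,0.73,,0.73,0.73,0
KO_WD,2,2,0.8,0.12,0.7,0.9,0
KO_WD,3,2,0.7,0.08,1.0,1.1,1
KO_WD,4,2,1.07,0.1,1.0,1.1,0
KO_WD,5,3,0.97,0.3,0.6,1.2,0
KO_WD,6,4,1.25,0.2,1.1,1.6,0
KO_WD,7,1,0.85,,0.85,0.85,0
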