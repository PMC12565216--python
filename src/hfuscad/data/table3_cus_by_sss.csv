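group,cus_total,sss_total,count
WT_SD,0,0,6
WT_SD,1,0,1
KO_SD,0,0,3
KO_SD,1,2,1
KO_SD,2,0,1
KO_SD,2,2,1
KO_SD,2,3,1
WT_WD,1,0,4
WT_WD,1,1,3
WT_WD,1,2,1
WT_WD,2,1,1
WT_WD,2,2,3
WT_WD,2,3,2
WT_WD,4,3,1
WT_WD,5,7,1
KO_WD,1,1,1
KO_WD,3,2,1
KO_WD,3,3,1
KO_WD,3,4,1
KO_WD,3,5,1
KO_WD,3,6,1
KO_WD,3,7,1
KO_WD,4,2,1
KO_WD,4,3,1
KO_WD,4,5,1
KO_WD,4,6,3
KO_WD,5,4,1
KO_WD,5,5,1
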