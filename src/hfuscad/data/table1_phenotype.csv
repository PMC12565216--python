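variable,group,mean,sd
bw_gain,WT_SD,120.5,15.5
bw_gain,WT_WD,151.4,35.7
bw_gain,KO_SD,100.1,18.7
bw_gain,KO_WD,147.5,68.8
energy_intake,WT_SD,239.4,18.1
energy_intake,WT_WD,262.8,28.3
energy_intake,KO_SD,305.4,72.9
energy_intake,KO_WD,358.8,185.7
fer,WT_SD,122.7,19.0
fer,WT_WD,147.4,38.1
fer,KO_SD,90.5,36.8
fer,KO_WD,144.95,80.3
bun,WT_SD,55.16,14.85
bun,WT_WD,20.4,5.0
bun,KO_SD,69.7,57.8
bun,KO_WD,42.3,10.5
creatinine,WT_SD,0.23,0.07
creatinine,WT_WD,0.19,0.1
creatinine,KO_SD,0.37,0.12
creatinine,KO_WD,0.22,0.1
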