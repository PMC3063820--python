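enzyme,substrate,km_uM,kcat_per_s,stoichiometry,assumed
FDS1,IDP,29.4,0.7,1,false
FDS1,GDP,17.2,,1,false
ADS,FDP,2,0.004,1,false
DBR2,AA,19,2.6,1,false
ALDH1,DHAA,8.8,7.7,1,false
ALDH1,AA,2.6,1.5,1,false
RED1,DHAA,67,0.28,1,false
CYP71AV1,AD,,,1,false
SQS,FDP,,1.0,2,true
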