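gene,efficiency,fragment_bp
beta-actin,1.91,180
ADS,1.88,95
ALDH1,1.82,120
CPR,1.90,174
CPS,1.85,150
CYP71AV1,1.83,144
DBR2#,1.91,228
DBR2+OPR3,1.84,125
DXR,1.92,160
DXS,1.92,120
ECS,1.86,126
FDS1/FDS2,1.93,92
GAS,1.83,147
HDR,1.86,95
HMGR,1.83,136
PAL,1.87,97
RED1,1.92,118
SQS,1.82,190
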