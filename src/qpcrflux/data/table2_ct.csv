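gene,flower_buds,young_leaves,old_leaves,stems,roots,hairy_roots
beta-actin,23.8,22.3,23.4,21.6,22.9,21.1
beta-actin#,20.8,22.1,22.5,20.7,24.4,20.3
ADS,23.3,22.2,29.9,30.0,n.d.,35.9
ALDH1,25.8,27.7,31.7,34.3,37.4,39.5
CPR,21.5,21.0,19.9,19.5,20.7,21.0
CPS,27.9,27.5,31.4,30.3,35.5,37.7
CYP71AV1,26.9,24.2,33.8,30.6,31.3,30.7
DBR2#,19.9,20.1,27.2,26.4,27.9,29.6
DBR2+OPR3,23.8,23.0,24.4,23.0,23.8,25.1
DXR,24.6,24.7,24.8,23.8,25.6,23.4
DXS,21.9,20.8,23.0,21.1,22.6,23.1
ECS,28.1,25.7,20.6,29.1,30.5,35.6
FDS1/FDS2,24.6,23.5,23.5,23.8,25.3,23.5
GAS,30.6,25.1,32.6,34.2,32.6,34.0
HDR,24.4,22.4,19.7,22.4,25.4,24.3
HMGR,24.6,24.4,28.6,24.6,23.8,24.7
PAL,21.8,20.0,21.3,19.4,20.8,21.7
RED1,31.7,30.7,26.0,34.6,25.7,20.9
SQS,26.7,26.5,25.2,25.1,26.5,25.7
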