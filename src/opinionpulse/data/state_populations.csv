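region,population
AL,4779736
AZ,6392017
AR,2915918
CA,37253956
CO,5029196
CT,3574097
DE,897934
DC,601723
FL,18801310
GA,9687653
ID,1567582
IL,12830632
IN,6483802
IA,3046355
KS,2853118
KY,4339367
LA,4533372
ME,1328361
MD,5773552
MA,6547629
MI,9883640
MN,5303925
MS,2967297
MO,5988927
MT,989415
NE,1826341
NV,2700551
NH,1316470
NJ,8791894
NM,2059179
NY,19378102
NC,9535483
ND,672591
OH,11536504
OK,3751351
OR,3831074
PA,12702379
RI,1052567
SC,4625364
SD,814180
TN,6346105
TX,25145561
UT,2763885
VT,625741
VA,8001024
WA,6724540
WV,1852994
WI,5686986
WY,563626
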