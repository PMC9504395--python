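name,white,black,api,aian,two_prace,hispanic
Smith,70.9,23.11,0.5,0.89,2.19,2.4
Washington,5.17,87.53,0.3,0.68,3.78,2.54
Chen,1.4,0.3,96.12,0.02,1.64,0.52
Beyale,1.89,0,0,94.7,0,1.89
KANEKOA,10.28,0,25.23,0,58.88,5.61
CEBALLOS,3.97,0.33,1.13,0.24,0.32,94.01
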