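region,population
white,223553265
black,38929319
api,15214265
aian,2932248
two_prace,9009073
hispanic,50477594
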