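label,q,p,source
S90,0.111,0,nominal
S85,0.118,0.118,nominal
S58,0.638,0.172,nominal
S90,0.101,0,analysed
S85,0.125,0.051,analysed
S58,0.659,0.148,analysed
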