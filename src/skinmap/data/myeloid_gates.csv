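label,CD45,CD207,CD1c,HLA-DR,CD123,Siglec8,MPO,Tryptase
Mast cell,+,.,.,.,.,.,.,+
dDC HLA-DRlow,+,-,+,low,.,.,.,.
dDC HLA-DRhigh,+,-,+,high,.,.,.,.
LC HLA-DRlow,+,+,-,low,.,.,.,.
LC HLA-DRhigh,+,+,-,high,.,.,.,.
CD207+ dDC HLA-DRlow,+,+,+,low,.,.,.,.
CD207+ dDC HLA-DRhigh,+,+,+,high,.,.,.,.
Neutrophil,+,-,-,.,.,-,+,-
Eosinophil,+,-,-,.,-,+,-,-
Basophil,+,-,-,.,+,+,-,.
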