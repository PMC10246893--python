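label,CD45,CD3,CD4,CD8,TCRgd,CD20,CD57
B cell,+,.,.,.,.,+,.
NK cell,+,-,.,.,.,-,+
CD4 T CD57low,+,+,+,-,-,-,low
CD4 T CD57high,+,+,+,-,-,-,high
CD8 T CD57low,+,+,-,+,-,-,low
CD8 T CD57high,+,+,-,+,-,-,high
gd T cell,+,+,.,.,+,-,.
dn T cell,+,+,-,-,-,-,.
dp T cell,+,+,+,+,-,-,.
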