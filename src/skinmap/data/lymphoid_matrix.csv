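marker,B cell,NK cell,CD4 T CD57low,CD4 T CD57high,CD8 T CD57low,CD8 T CD57high,gd T cell,gd T cell#2,dn T cell,dp T cell
CD45,1,1,1,1,1,1,1,1,1,1
CD3,0,0,1,1,1,1,1,1,1,1
CD4,0,0,1,1,0,0,0,1,0,1
CD8,0,0,0,0,1,1,0,0,0,1
TCRgd,0,0,0,0,0,0,1,1,0,0
CD20,1,0,0,0,0,0,0,0,0,0
CD57,0,1,0,1,0,1,0,0,0,0
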