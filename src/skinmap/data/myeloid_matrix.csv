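marker,Mast cell,Neutrophil,Eosinophil,Basophil,dDC HLA-DRlow,dDC HLA-DRhigh,LC HLA-DRlow,LC HLA-DRhigh,CD207+ dDC HLA-DRlow,CD207+ dDC HLA-DRhigh
CD45,1,1,1,1,1,1,1,1,1,1
CD207,0,0,0,0,0,0,1,1,1,1
CD1c,0,0,0,0,1,1,0,0,1,1
HLA-DR,0,0,0,0,0,1,0,1,0,1
CD123,0,0,0,1,0,0,0,0,0,0
Siglec8,0,0,1,1,0,0,0,0,0,0
MPO,0,1,0,0,0,0,0,0,0,0
Tryptase,1,0,0,0,0,0,0,0,0,0
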