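yl
ol
al
ate
ine
ide
ane
ene
ose
oate
azol
amid
diol
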