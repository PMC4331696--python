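di
az
cy
tri
iso
oxo
aza
fluo
chlo
brom
nitr
hydr
cycl
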