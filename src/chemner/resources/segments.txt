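acet
oxy
actin
idine
methyl
ergo
novi
interleukin
poly
calcium
meth
estra
di
ol
toxin
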