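species
PERMAN
PERKEE
SORTRO
SORVAG
SORSPP
GLAORE
TAMHUD
NEOTOW
MICORE
NEOCIN
MYOCAL
DIDVIR
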