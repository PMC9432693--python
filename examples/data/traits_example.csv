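species,mass_g,diet,stratum
PERMAN,20.5,granivore_mycophage,ground
SORTRO,5.0,insectivore,ground
SORVAG,5.5,insectivore,ground
GLAORE,120.0,granivore_mycophage,arboreal
TAMHUD,212.0,granivore_mycophage,arboreal
NEOTOW,75.0,granivore_mycophage,semi_arboreal
MICORE,19.0,granivore_mycophage,ground
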