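block,stand,treatment,subplot,cover_type,patch_context,year,week,occasion,species,individual_tag,tail_mm,mass_g
B01,B01-RA,RA,B01-RA-G1,patch,riparian,1,3,1,PERMAN,PM-0001,70.0,21.5
B01,B01-RA,RA,B01-RA-G1,patch,riparian,1,3,3,PERMAN,PM-0001,70.0,21.5
B01,B01-RA,RA,B01-RA-G2,clearcut,none,1,3,1,PERMAN,PM-0002,68.0,19.0
B01,B01-RA,RA,B01-RA-G1,patch,riparian,1,3,2,SORTRO,,51.0,4.9
B01,B01-RA,RA,B01-RA-G1,patch,riparian,1,3,4,SORTRO,,49.5,5.2
B01,B01-RA,RA,B01-RA-G1,patch,riparian,1,3,2,GLAORE,GO-0001,,120.3
B01,B01-RA,RA,B01-RA-G2,clearcut,none,1,3,4,NEOTOW,NT-0001,,72.0
B01,B01-UA,UA,B01-UA-G1,patch,upland,1,4,1,MICORE,MO-0001,,18.7
B01,B01-UA,UA,B01-UA-G2,clearcut,none,1,4,2,PERMAN,PM-0003,66.0,18.2
B01,B01-UA,UA,B01-UA-G2,clearcut,none,1,4,3,SORVAG,,38.0,5.5
B01,B01-ROT,ROT,B01-ROT-G1,rotation,none,1,5,1,TAMHUD,TH-0001,,210.0
B01,B01-ROT,ROT,B01-ROT-G1,rotation,none,1,5,2,GLAORE,GO-0002,,118.0
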