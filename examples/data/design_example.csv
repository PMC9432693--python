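unit,block,stand,treatment,subplot,cover_type,patch_context,subplot_class,n_traps,year,week,occasions_sampled
B01-RA-G1:1,B01,B01-RA,RA,B01-RA-G1,patch,riparian,riparian_patch,48,1,3,4
B01-RA-G2:1,B01,B01-RA,RA,B01-RA-G2,clearcut,none,clearcut,48,1,3,4
B01-UA-G1:1,B01,B01-UA,UA,B01-UA-G1,patch,upland,upland_patch,48,1,4,4
B01-UA-G2:1,B01,B01-UA,UA,B01-UA-G2,clearcut,none,clearcut,48,1,4,4
B01-ROT-G1:1,B01,B01-ROT,ROT,B01-ROT-G1,rotation,none,rotation,48,1,5,4
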