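# Reduced synthetic experiment: 2 blocks of 5 retention treatments plus two
# rotation-aged stands, 8 species over 2 summers.  All other parameters keep
# the study-scale defaults (abundance skew, detection ~0.33/night, riparian
# effect for arboreal species).
n_blocks: 2
n_rotation_stands: 2
n_species: 8
n_years: 2
missingness: false
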