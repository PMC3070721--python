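# taxon	display_group
# Known phototrophic / exclusively planktonic taxa used to flag OTUs of
# planktonic origin.  The Dinophyceae and Radiolaria entries stand for the
# phototrophic/symbiont-bearing genera of those groups; user-supplied genus
# lists can extend this table.
Dinophyceae_phototrophic	Dinophyceae
Chlorophyta	Plantae
Rhodophyta	Plantae
Glaucophyta	Plantae
Haptophyta	Haptophyta
Picobiliphyta	Picobiliphyta
Radiolaria	Radiolaria
Bacillariophyta	Bacillariophyta
Bolidophyceae	Bolidophyceae
Dictyochophyceae	Dictyochophyceae
Pelagophyceae	Pelagophyceae
Phaeophyceae	Phaeophyceae
Phaeothamniophyceae	Phaeothamniophyceae
Pinguiophyceae	Pinguiophyceae
Raphidophyceae	Raphidophyceae
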