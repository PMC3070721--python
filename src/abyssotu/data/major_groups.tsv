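# lineage name	major group category
# The deepest matching lineage name wins, so Ciliophora beats Alveolata.
Ciliophora	Ciliophora
Dinophyceae	Dinophyceae
Alveolata	other Alveolata
Amoebozoa	Amoebozoa
Euglenozoa	Euglenozoa
Heterolobosea	other Eukarya
Fungi	Fungi
Metazoa	Metazoa
Choanoflagellata	other Opisthokonta
Ichthyosporea	other Opisthokonta
Opisthokonta	other Opisthokonta
Chlorophyta	Plantae
Rhodophyta	Plantae
Glaucophyta	Plantae
Plantae	Plantae
Cercozoa	Cercozoa
Foraminifera	other Rhizaria
Radiolaria	other Rhizaria
Rhizaria	other Rhizaria
Bacillariophyta	Bacillariophyta
Chrysophyceae	Chrysophyceae
Labyrinthulea	Labyrinthulea
Pelagophyceae	other Stramenopiles
Dictyochophyceae	other Stramenopiles
Bolidophyceae	other Stramenopiles
Phaeophyceae	other Stramenopiles
Phaeothamniophyceae	other Stramenopiles
Pinguiophyceae	other Stramenopiles
Raphidophyceae	other Stramenopiles
Stramenopiles	other Stramenopiles
Cryptophyta	CCTH
Haptophyta	CCTH
Telonemia	CCTH
Centroheliozoa	CCTH
Apusozoa	other Eukarya
Katablepharida	other Eukarya
Picobiliphyta	other Eukarya
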