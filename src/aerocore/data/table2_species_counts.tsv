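city	kingdom	n_species
All	Bacteria	2560
All	Fungi	956
All	Virus	36
All	Archaea	25
Denver	Bacteria	776
Denver	Fungi	199
Denver	Virus	2
Denver	Archaea	3
Hong Kong	Bacteria	1931
Hong Kong	Fungi	653
Hong Kong	Virus	14
Hong Kong	Archaea	12
London	Bacteria	836
London	Fungi	276
London	Virus	4
London	Archaea	16
New York	Bacteria	1237
New York	Fungi	413
New York	Virus	8
New York	Archaea	15
Oslo	Bacteria	969
Oslo	Fungi	442
Oslo	Virus	1
Oslo	Archaea	17
Stockholm	Bacteria	590
Stockholm	Fungi	213
Stockholm	Virus	2
Stockholm	Archaea	6
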