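taxon	F=0.8 Pa	F=1.29 Pa	F=2.0 Pa
Archaea_unclassified	0.97	0.02	0.01
DHVEG-6	76.15	42.53	25.76
Euryarchaeota_unclassified	0.89	0.09	0.01
MBG-B_norank	1.25	0.23	0.03
Methanobacterium	0.26	0.02	0
Methanoregula	0.4	0.04	0.32
Methanosphaerula	0.04	0	0.01
Methanospirillum	19.87	57.07	78.84
TMEG	0.06	0	0.02
Thermoprotei_unclassified	0.11	0	0
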