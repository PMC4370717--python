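species_id	ssi	sti	ssig
Perdix perdix	1.31	1.10	1.25
Motacilla flava	1.19	2.00	1.33
Miliaria calandra	1.08	1.28	1.56
Vanellus vanellus	1.55	1.90	1.56
Carduelis chloris	0.86	1.05	1.58
Coturnix coturnix	1.21	1.22	1.59
Alauda arvensis	1.13	1.25	1.60
Carduelis carduelis	0.67	1.05	1.66
Alectoris rufa	0.69	1.10	1.84
Carduelis cannabina	0.62	1.05	1.85
Corvus frugilegus	0.92	1.63	1.94
Anthus pratensis	1.33	1.75	2.00
Sylvia communis	0.63	1.60	2.04
Falco tinnunculus	0.48	2.85	2.12
Emberiza citrinella	0.54	1.30	2.26
Saxicola torquatus	0.66	2.00	2.29
Emberiza cirlus	0.39	1.30	2.37
Buteo buteo	0.39	2.90	2.42
Saxicola rubetra	1.23	2.00	2.44
Upupa epops	0.29	2.00	2.53
Lanius collurio	0.87	2.15	2.58
Lullula arborea	0.58	1.50	2.61
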