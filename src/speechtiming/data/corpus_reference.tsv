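language	family	iso	n_nuclei	n_phrases	median_ini_ms	ks_d	npvi	lr_ini_mean	lr_ini_variance	differential_entropy	best_p	best_q	best_d	akaike_set_size	d1_weight_percent
Arabic	Afro-Asiatic	ara	211	15	173	0.07	38.6	0.02	0.25	0.72	5	3	1	30	93.96
Arrernte	Pama-Nyungan	aer	220	18	177	0.074	35.4	-0.02	0.23	0.70	1	1	1	21	98.89
Cantonese	Sino-Tibetan	yue	123	20	144	0.076	26.8	0.06	0.11	0.35	0	0	0	30	7.62
Dutch	Indo-European	nld	159	18	148	0.078	45.9	0.04	0.33	0.87	2	3	1	19	99.12
Georgian	Kartvelian	kat	173	18	164	0.113	47.8	0.01	0.41	0.98	0	1	1	19	99.99
Hindi	Indo-European	hin	211	23	179	0.033	33.8	0.00	0.19	0.59	0	1	1	34	91.14
Hungarian	Uralic	hun	191	13	188	0.037	37.3	0.02	0.22	0.68	0	1	1	50	65.05
Igbo	Niger-Congo	ibo	159	23	194	0.139	39	0.01	0.25	0.74	0	1	1	16	100.00
Italian	Indo-European	ita	185	20	185	0.056	41	0.04	0.27	0.76	2	3	1	21	99.83
Japanese	Japonic	jpn	187	24	131	0.163	49.2	0.10	0.35	0.90	0	1	1	21	100.00
Kunama	Nilo-Saharan	kun	185	41	196	0.078	41	0.09	0.28	0.80	0	1	1	17	100.00
Mapudungun	Araucanian	arn	161	24	211	0.109	38.1	-0.01	0.25	0.73	2	3	1	21	99.94
Nuuchahnulth	Wakashan	nuk	106	13	285	0.077	47.7	0.04	0.47	1.05	0	1	1	21	99.99
Spokane	Salishan	spo	92	11	364	0.11	42.3	0.01	0.34	0.88	1	1	1	20	100.00
Tena Quichua	Quechuan	quw	238	36	249	0.112	42.3	-0.03	0.35	0.91	0	3	1	22	98.43
Thai	Tai-Kadai	tha	181	33	251	0.064	41	0.02	0.33	0.87	3	2	1	21	99.99
Turkish	Turkic	tur	169	14	159	0.055	32.9	0.00	0.17	0.54	2	4	1	45	60.02
Vietnamese	Austroasiatic	vie	121	19	214	0.086	36.8	0.07	0.24	0.71	0	1	1	19	98.19
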