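species	group	n_individuals	partition	n_loci	gst	p_gst	gst_jack_mean	gst_jack_halfwidth	nst	p_nst	nst_jack_mean	nst_jack_halfwidth	p_nst_gt_gst
Antitrichia curtipendula	bryophyte	37	both	2	0.05	0.28	0.05	0.04	0.06	0.18	0.09	0.06	0.21
Antitrichia curtipendula	bryophyte	37	nDNA	1	0.03	0.34	NA	NA	0.07	0.27	NA	NA	0.48
Antitrichia curtipendula	bryophyte	37	cpDNA	1	0.07	0.63	NA	NA	0.00	0.01	NA	NA	0.33
Amphidium mougeotii	bryophyte	52	nDNA	2	0.02	0.49	0.02	0.06	0.00	0.69	0.00	0.00	0.29
Calypogeia fissa	bryophyte	26	cpDNA	1	0.04	0.52	NA	NA	0.01	0.76	NA	NA	0.83
Homalothecium sericeum	bryophyte	46	cpDNA	1	0.11	0.03	NA	NA	0.08	0.06	NA	NA	0.86
Metzgeria furcata	bryophyte	59	cpDNA	1	0.00	0.82	NA	NA	0.00	0.60	NA	NA	0.63
Lewinskya affine	bryophyte	57	both	4	0.05	0.17	0.05	0.10	0.03	0.28	0.03	0.05	0.44
Lewinskya affine	bryophyte	57	nDNA	3	0.06	0.15	0.06	0.11	0.03	0.25	0.03	0.05	0.45
Lewinskya affine	bryophyte	57	cpDNA	1	0.00	0.88	NA	NA	0.00	0.88	NA	NA	0.20
Plagiomnium undulatum	bryophyte	57	both	3	0.21	0.00	0.20	0.17	0.34	0.00	0.35	0.07	0.03
Plagiomnium undulatum	bryophyte	57	nDNA	2	0.30	0.00	0.30	0.05	0.37	0.00	0.37	0.03	0.03
Plagiomnium undulatum	bryophyte	57	cpDNA	1	0.08	0.37	NA	NA	0.13	0.29	NA	NA	0.48
Plagiothecium undulatum	bryophyte	42	nDNA	2	0.02	0.60	0.02	0.14	0.00	1.00	0.03	0.17	0.17
Pulvigera lyellii	bryophyte	81	both	4	0.26	0.00	0.28	0.46	0.28	0.00	0.31	0.46	0.52
Pulvigera lyellii	bryophyte	81	nDNA	3	0.02	0.44	0.02	0.04	0.04	0.15	0.05	0.09	0.35
Pulvigera lyellii	bryophyte	81	cpDNA	1	0.77	0.00	NA	NA	0.77	0.00	NA	NA	0.80
Scorpiurium circinatum	bryophyte	18	both	2	0.15	0.09	0.15	0.16	0.04	0.50	0.10	0.13	0.06
Scorpiurium circinatum	bryophyte	18	nDNA	1	0.22	0.05	NA	NA	0.05	0.50	NA	NA	0.07
Scorpiurium circinatum	bryophyte	18	cpDNA	1	0.06	0.48	NA	NA	0.00	0.86	NA	NA	0.14
Sphagnum fimbriatum	bryophyte	34	cpDNA	1	0.17	0.52	NA	NA	0.20	0.06	NA	NA	0.33
Arabis alpina	spermatophyte	38	both	2	0.00	0.71	0.00	0.04	0.07	0.17	0.08	0.04	0.05
Arabis alpina	spermatophyte	38	nDNA	1	NA	NA	NA	NA	NA	NA	NA	NA	NA
Arabis alpina	spermatophyte	38	cpDNA	1	0.00	0.85	NA	NA	0.05	0.44	NA	NA	0.13
Alnus glutinosa	spermatophyte	198	cpDNA	1	0.46	0.00	NA	NA	0.42	0.00	NA	NA	0.77
Aegilops geniculata	spermatophyte	63	cpDNA	1	0.08	0.09	NA	NA	0.22	0.01	NA	NA	0.35
Arabidopsis thaliana	spermatophyte	130	both	3	0.08	0.00	0.08	0.07	0.07	0.00	0.06	0.09	0.76
Arabidopsis thaliana	spermatophyte	130	nDNA	2	0.06	0.00	0.06	0.11	0.10	0.00	0.08	0.17	0.14
Arabidopsis thaliana	spermatophyte	130	cpDNA	1	0.18	0.00	NA	NA	0.02	0.18	NA	NA	0.03
Beta vulgaris maritima	spermatophyte	19	both	4	0.06	0.09	0.06	0.12	0.00	0.77	0.00	0.08	1.00
Beta vulgaris maritima	spermatophyte	19	nDNA	3	0.10	0.05	0.09	0.16	0.01	0.76	0.00	0.15	1.00
Beta vulgaris maritima	spermatophyte	19	cpDNA	1	0.00	0.73	NA	NA	0.00	0.69	NA	NA	0.53
Carex extensa	spermatophyte	52	cpDNA	1	0.25	0.01	NA	NA	0.25	0.01	NA	NA	1.00
Ceratonia siliqua	spermatophyte	124	cpDNA	1	0.51	0.00	NA	NA	0.55	0.00	NA	NA	0.16
Calluna vulgaris	spermatophyte	132	cpDNA	1	0.09	0.00	NA	NA	0.36	0.00	NA	NA	0.00
Hedera helix	spermatophyte	27	cpDNA	1	0.22	0.01	NA	NA	0.35	0.02	NA	NA	0.40
Hordeum marinum	spermatophyte	94	cpDNA	1	0.01	0.36	NA	NA	0.02	0.37	NA	NA	0.73
Helianthemum nummularium	spermatophyte	26	cpDNA	1	0.01	0.67	NA	NA	0.01	0.57	NA	NA	0.81
Lavatera maritima	spermatophyte	62	cpDNA	1	0.06	0.11	NA	NA	0.10	0.04	NA	NA	0.16
Myrtus communis	spermatophyte	158	both	3	0.02	0.07	0.03	0.05	0.04	0.23	0.05	0.07	0.82
Myrtus communis	spermatophyte	158	nDNA	2	0.02	0.07	0.03	0.07	0.04	0.19	0.05	0.07	0.83
Myrtus communis	spermatophyte	158	cpDNA	1	0.03	0.15	NA	NA	0.06	0.04	NA	NA	0.54
Microthlaspi perfoliatum	spermatophyte	153	both	2	0.30	0.00	0.33	0.22	0.21	0.00	0.21	0.02	1.00
Microthlaspi perfoliatum	spermatophyte	153	nDNA	1	0.15	0.00	NA	NA	0.21	0.00	NA	NA	0.22
Microthlaspi perfoliatum	spermatophyte	153	cpDNA	1	0.38	0.00	NA	NA	0.19	0.01	NA	NA	0.07
Primula vulgaris	spermatophyte	21	both	2	0.09	0.11	0.08	0.06	0.00	0.89	0.00	0.03	0.07
Primula vulgaris	spermatophyte	21	nDNA	1	0.12	0.21	NA	NA	0.00	0.93	NA	NA	0.05
Primula vulgaris	spermatophyte	21	cpDNA	1	0.06	0.31	NA	NA	0.02	0.75	NA	NA	0.79
Sedum album	spermatophyte	24	cpDNA	1	0.02	0.38	NA	NA	0.06	0.16	NA	NA	0.40
Silene nutans	spermatophyte	258	cpDNA	1	0.30	0.00	NA	NA	0.28	0.03	NA	NA	0.95
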