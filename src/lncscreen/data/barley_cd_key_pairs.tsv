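lncrna_id	lnc_log2fc_tolerant	lnc_log2fc_sensitive	target_id	target_log2fc_tolerant	target_log2fc_sensitive	annotation
TCONS_00005624	21.28	-4.23	TCONS_00005620	1.08	-0.48	Protein DJ-1 homolog B
TCONS_00071028	-1.08	-0.64	HORVU.MOREX.r2.6HG0471350.1	0.93	1.18	Cinnamoyl-CoA reductase 1
TCONS_00035202	0.96	1.20	TCONS_00013867	1.13	0.71	Transmembrane E3 ubiquitin-protein ligase
TCONS_00040227	-0.78	-1.27	TCONS_00065833	-0.54	-1.20	Protein ENHANCED DISEASE RESISTANCE 2
TCONS_00073318	-0.94	-1.23	HORVU.MOREX.r2.7HG0544860.1	-0.89	-1.15	HNHc domain-containing protein
TCONS_00078863	-0.91	-1.22	TCONS_00086237	1.03	0.76	ABC transporter C family member 13
TCONS_00029966	-0.97	-1.40	HORVU.MOREX.r2.1HG0013370.1	0.98	1.69	Peroxidase 2
TCONS_00029966	-0.97	-1.40	HORVU.MOREX.r2.4HG0320560.1	0.80	1.42	Probable glucuronosyltransferase Os03g0287800
TCONS_00029966	-0.97	-1.40	HORVU.MOREX.r2.4HG0340350.1	0.67	1.35	2-oxoglutarate-dependent dioxygenase 11
TCONS_00029966	-0.97	-1.40	HORVU.MOREX.r2.5HG0364740.1	0.60	1.37	Uncharacterized protein
TCONS_00029966	-0.97	-1.40	TCONS_00024166	0.48	1.12	Polygalacturonase QRT3
TCONS_00029966	-0.97	-1.40	TCONS_00043280	0.88	1.04	Low affinity sulfate transporter 3
TCONS_00031104	-0.63	-1.16	HORVU.MOREX.r2.7HG0620250.1	-0.77	-1.02	Putrescine hydroxycinnamoyltransferase 1
TCONS_00086719	-0.77	-1.05	TCONS_00016866	0.78	1.48	Galacturonokinase
TCONS_00017042	-0.75	-1.16	HORVU.MOREX.r2.7HG0605000.1	0.93	1.52	Luminal-binding protein 3
TCONS_00047478	-0.92	-1.08	HORVU.MOREX.r2.2HG0112600.1	-0.91	-1.06	Mixed-linked glucan synthase 4
TCONS_00007510	-0.61	-1.49	TCONS_00022788	-0.57	-1.19	Alpha-glucan phosphorylase 1
TCONS_00007510	-0.61	-1.49	TCONS_00075108	1.01	0.99	Oligopeptide transporter 7
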