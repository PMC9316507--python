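circ_id	mirna_id	prediction_score	binding_motif
circ-PRMT1-1	miR-6754-3p	80	GGUGAAGA
circ-PRMT1-1	miR-494-3p	76	AUGUUUCA
circ-PRMT1-2	miR-6754-3p	77	GGUGAAGA
circ-PRMT1-2	miR-494-3p	76	AUGUUUCA
circ-PRMT1-3	miR-494-3p	76	AUGUUUCA
circ-PRMT1-3	miR-6754-3p	68	GGUGAAGA
circ-PRMT1-4	miR-494-3p	76	AUGUUUCA
circ-PRMT1-4	miR-6754-3p	68	GGUGAAGA
circ-PRMT1-5	miR-494-3p	75	AUGUUUCA
circ-PRMT1-5	miR-6754-3p	67	GGUGAAGA
circ-PRMT1-6	miR-494-3p	78	AUGUUUCA
circ-PRMT1-6	miR-6754-3p	73	GGUGAAGA
circ-PRMT1-7	miR-494-3p	76	AUGUUUCA
circ-PRMT1-7	miR-1306-3p	66	GGAGGUG
circ-PRMT1-8	miR-4745-3p	65	CCGGGCCA
circ-PRMT1-8	miR-1538-3p	62	CCGGGCCA
circ-PRMT1-9	miR-4696-5p	86	GUCUUGCA
circ-PRMT1-9	miR-588-5p	71	GUGGCCA
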