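circ_id	accession	cell_lines	exon_count	exons	length_nt
circ-PRMT1-1	ON081037	MDA-MB-468	5	Exon 1, Exon 4, Exon 5, Exon 6, Exon 7 *	410
circ-PRMT1-2	ON081038	MDA-MB-468	5	Exon 1, Exon 4, Exon 5, Exon 6, Exon 7 *	447
circ-PRMT1-3	ON081039	MDA-MB-468	5	Exon 3 *, Exon 4, Exon 5, Exon 6, Exon 7 *	462
circ-PRMT1-4	ON081040	MDA-MB-468	5	Exon 3 *, Exon 4, Exon 5, Exon 6, Exon 7 *	447
circ-PRMT1-5	ON081041	MDA-MB-468	6	Exon 3 *, Exon 4, Exon 5, Exon 6, Exon 7, Exon 8 *	551
circ-PRMT1-6	ON081042	Mix of BT-20, MCF-7, MDA-MB-231, MDA-MB-468	2	Exon 6, Exon 5 *	204
circ-PRMT1-7	ON081043	BT-20, MCF-7	4	Exon 1 *, Exon 4, Exon 5, Exon 6 *	330
circ-PRMT1-8	ON081044	Mix of BT-20, MCF-7, MDA-MB-231, MDA-MB-468	3	Exon 6 *, Exon 7, Exon 8 *	234
circ-PRMT1-9	ON081045	Mix of BT-20, MCF-7, MDA-MB-231, MDA-MB-468	4	Exon 7 *, Exon 8, Exon 9, Exon 10 *	348
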