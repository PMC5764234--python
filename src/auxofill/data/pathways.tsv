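amino_acid	variant_id	step_index	reaction_id
his	v1	1	ATP-PRTRANS
his	v1	2	PRATP-PPASE
his	v1	3	PRAMP-CH
his	v1	4	PRFAR-ISOM
his	v1	5	IGP-SYNTH
his	v1	6	IGP-DEHYDRATASE
his	v1	7	HISOLP-AT
his	v1	8	HISOLP-PPASE
his	v1	9	HISOL-DH
ser	v1	1	PGDH
ser	v1	2	PSER-AT
ser	v1	3	PSER-PPASE
thr	v1	1	ASP-KINASE
thr	v1	2	ASA-DH
thr	v1	3	HSER-DH
thr	v1	4	HSER-KINASE
thr	v1	5	THR-SYNTH
met	v1_succinyl	1	ASP-KINASE
met	v1_succinyl	2	ASA-DH
met	v1_succinyl	3	HSER-DH
met	v1_succinyl	4	HSER-SUCCTRANS
met	v1_succinyl	5	CYSTATHIONINE-GS
met	v1_succinyl	6	CYSTATHIONINE-BL
met	v1_succinyl	7	MET-SYNTH
met	v2_direct_sulfuration	1	ASP-KINASE
met	v2_direct_sulfuration	2	ASA-DH
met	v2_direct_sulfuration	3	ASA-SULFTRANS
met	v2_direct_sulfuration	4	MET-SYNTH
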