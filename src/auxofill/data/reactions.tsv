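reaction_id	name	is_transaminase
ATP-PRTRANS	ATP phosphoribosyltransferase	False
PRATP-PPASE	phosphoribosyl-ATP diphosphatase	False
PRAMP-CH	phosphoribosyl-AMP cyclohydrolase	False
PRFAR-ISOM	ProFAR isomerase	False
IGP-SYNTH	imidazole-glycerol-phosphate synthase	False
IGP-DEHYDRATASE	imidazoleglycerol-phosphate dehydratase	False
HISOLP-AT	histidinol-phosphate transaminase	True
HISOLP-PPASE	histidinol-phosphate phosphatase	False
HISOL-DH	histidinol dehydrogenase	False
PGDH	D-3-phosphoglycerate dehydrogenase	False
PSER-AT	phosphoserine transaminase	True
PSER-PPASE	phosphoserine phosphatase	False
ASP-KINASE	aspartate kinase	False
ASA-DH	aspartate-semialdehyde dehydrogenase	False
HSER-DH	homoserine dehydrogenase	False
HSER-KINASE	homoserine kinase	False
THR-SYNTH	threonine synthase	False
HSER-SUCCTRANS	homoserine O-succinyltransferase	False
CYSTATHIONINE-GS	cystathionine gamma-synthase	False
CYSTATHIONINE-BL	cystathionine beta-lyase	False
ASA-SULFTRANS	aspartate-semialdehyde reductive sulfuration	False
MET-SYNTH	methionine synthase	False
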