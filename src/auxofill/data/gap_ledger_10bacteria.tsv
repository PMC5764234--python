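group	subgroup	cases
Clear candidate	multiple candidates	9
Clear candidate	auxotrophic	61
Clear candidate	essential	54
Clear candidate	no fitness data	9
Clear candidate	other (redundant)	5
Clear candidate	other	2
Gene model error		2
Transaminase		18
Known gap		2
Genuine gap	filled (this study)	9
Genuine gap	unfilled	2
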