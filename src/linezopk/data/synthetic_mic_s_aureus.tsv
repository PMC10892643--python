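# pathogen: Staphylococcus aureus [SYNTHETIC toy distribution, not EUCAST data]
mic_mg_per_L	fraction
0.5	0.10
1	0.45
2	0.35
4	0.10
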