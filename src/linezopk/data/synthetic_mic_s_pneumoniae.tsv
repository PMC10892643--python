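# pathogen: Streptococcus pneumoniae [SYNTHETIC toy distribution, not EUCAST data]
mic_mg_per_L	fraction
0.25	0.35
0.5	0.65
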