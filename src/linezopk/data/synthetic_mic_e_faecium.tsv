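# pathogen: Enterococcus faecium [SYNTHETIC toy distribution, not EUCAST data]
mic_mg_per_L	fraction
1	0.15
2	0.40
4	0.35
8	0.10
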