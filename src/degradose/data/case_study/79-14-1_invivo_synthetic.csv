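# provenance: in_vivo
# label: synthetic reconstruction of the first-week in vivo mass loss of the glycolide-containing copolymer (worst observed 7-day loss 2%)
t_days,fraction_lost
0,0.0
3.5,0.01
7,0.02
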