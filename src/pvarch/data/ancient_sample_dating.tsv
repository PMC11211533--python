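timing_bp	count
>=10,000	128
8,000–9,999	133
6,000–7,999	579
4,000–5,999	969
2,000–3,999	2002
<2,000	928
NA	292
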