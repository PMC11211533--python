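population	cases
Non-Finnish European	90914
East Asian	61111
Latino/Admixed American	24943
South Asian	17727
Finnish	16140
Ashkenazi Jewish	6776
Other	4117
Amish	456
Middle Eastern	158
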