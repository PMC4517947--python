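sample_id	age_days	density
P14	14	1.86
P17	17	2.41
P19	19	3.30
P21	21	2.70
P22	22	2.83
P23	23	2.50
P24	24	3.07
P26	26	2.25
P28	28	1.95
P30	30	1.85
P32	32	1.48
P33	33	2.51
P34	34	2.43
P36	36	2.11
P38	38	1.91
P40	40	1.64
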