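label	outcome	replaced	n	beta	lo	hi
MONICA	dBW	carbohydrate	1257	123.4	30.4	216.4
DCH	dBW	carbohydrate	2167	-11.6	-102.6	79.5
INTER99	dBW	carbohydrate	3630	19.0	-47.6	85.6
MONICA	dBW	fat	1257	56.3	-31.9	144.4
DCH	dBW	fat	2167	54.5	-45.1	154.1
INTER99	dBW	fat	3630	15.2	-54.1	84.5
DCH	dWC	carbohydrate	2128	-0.7	-1.8	0.4
INTER99	dWC	carbohydrate	3160	0.5	-0.1	1.0
DCH	dWC	fat	2167	-0.8	-2.0	0.4
INTER99	dWC	fat	3160	0.5	-0.1	1.1
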