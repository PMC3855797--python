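peak_id	structure_code	fucosylated	bisecting	gal_count	sial_count	conventional
GP1	A1	0	0	0	0	1
GP2	A2	0	0	0	0	1
GP3	A2B	0	1	0	0	1
GP4	FA2	1	0	0	0	0
GP5	M5	0	0	0	0	1
GP6	FA2B	1	1	0	0	1
GP7	A2[6]G1	0	0	1	0	1
GP8	FA2[6]G1	1	0	1	0	0
GP9	FA2[3]G1	1	0	1	0	0
GP10	FA2[6]BG1	1	1	1	0	1
GP11	FA2[3]BG1	1	1	1	0	1
GP12	A2G2	0	0	2	0	1
GP13	A2BG2	0	1	2	0	1
GP14	FA2G2	1	0	2	0	0
GP15	FA2BG2	1	1	2	0	1
GP16	FA2[3]G1S1	1	0	1	1	1
GP17	FA2[6]G1S1	1	0	1	1	1
GP18	FA2G2S1	1	0	2	1	1
GP19	FA2BG2S1	1	1	2	1	1
GP20	A2G2S1	0	0	2	1	1
GP21	A2G2S2	0	0	2	2	0
GP22	A2BG2S2	0	1	2	2	1
GP23	FA2G2S2	1	0	2	2	1
GP24	FA2BG2S2	1	1	2	2	1
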