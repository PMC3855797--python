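name	numerator	denominator	scale
GP1	GP1	1	raw
GP2	GP2	1	raw
GP4	GP4	1	raw
GP5	GP5	1	raw
GP6	GP6	1	raw
GP7	GP7	1	raw
GP8	GP8	1	raw
GP9	GP9	1	raw
GP10	GP10	1	raw
GP11	GP11	1	raw
GP12	GP12	1	raw
GP13	GP13	1	raw
GP14	GP14	1	raw
GP15	GP15	1	raw
GP16	GP16	1	raw
GP17	GP17	1	raw
GP18	GP18	1	raw
GP19	GP19	1	raw
GP21	GP21	1	raw
GP22	GP22	1	raw
GP23	GP23	1	raw
GP24	GP24	1	raw
FGS/(FG+FGS)	FGS	FG+FGS	percent
FBGS/(FBG+FBGS)	FBGS	FBG+FBGS	percent
FGS/(F+FG+FGS)	FGS	F+FG+FGS	percent
FBGS/(FB+FBG+FBGS)	FBGS	FB+FBG+FBGS	percent
FG1S1/(FG1+FG1S1)	FG1S1	FG1+FG1S1	percent
FG2S1/(FG2+FG2S1+FG2S2)	FG2S1	FG2+FG2S1+FG2S2	percent
FG2S2/(FG2+FG2S1+FG2S2)	FG2S2	FG2+FG2S1+FG2S2	percent
FBG2S1/(FBG2+FBG2S1+FBG2S2)	FBG2S1	FBG2+FBG2S1+FBG2S2	percent
FBG2S2/(FBG2+FBG2S1+FBG2S2)	FBG2S2	FBG2+FBG2S1+FBG2S2	percent
FtotalS1/FtotalS2	FtotalS1	FtotalS2	ratio
FS1/FS2	FS1	FS2	ratio
FBS1/FBS2	FBS1	FBS2	ratio
FBStotal/FStotal	FBStotal	FStotal	ratio
FBS1/FS1	FBS1	FS1	ratio
FBS1/(FS1+FBS1)	FBS1	FS1+FBS1	ratio
FBS2/FS2	FBS2	FS2	ratio
FBS2/(FS2+FBS2)	FBS2	FS2+FBS2	ratio
GP1n	GP1n	1	raw
GP2n	GP2n	1	raw
GP4n	GP4n	1	raw
GP5n	GP5n	1	raw
GP6n	GP6n	1	raw
GP7n	GP7n	1	raw
GP8n	GP8n	1	raw
GP9n	GP9n	1	raw
GP10n	GP10n	1	raw
GP11n	GP11n	1	raw
GP12n	GP12n	1	raw
GP13n	GP13n	1	raw
GP14n	GP14n	1	raw
GP15n	GP15n	1	raw
G0n	G0n	1	raw
G1n	G1n	1	raw
G2n	G2n	1	raw
Fn total	Fntotal	1	raw
FG0n total/G0n	FG0ntotal	G0n	percent
FG1n total/G1n	FG1ntotal	G1n	percent
FG2n total/G2n	FG2ntotal	G2n	percent
Fn	Fn	1	raw
FG0n/G0n	FG0n	G0n	percent
FG1n/G1n	FG1n	G1n	percent
FG2n/G2n	FG2n	G2n	percent
FBn	FBn	1	raw
FBG0n/G0n	FBG0n	G0n	percent
FBG1n/G1n	FBG1n	G1n	percent
FBG2n/G2n	FBG2n	G2n	percent
FBn/Fn	FBn	Fn	ratio
FBn/Fn total	FBn	Fntotal	percent
Fn/(Bn + FBn)	Fn	Bn+FBn	ratio
Bn/(Fn + FBn) ‰	Bn	Fn+FBn	permille
FBG2n/FG2n	FBG2n	FG2n	ratio
FBG2n/(FG2n + FBG2n)	FBG2n	FG2n+FBG2n	percent
FG2n/(BG2n + FBG2n)	FG2n	BG2n+FBG2n	ratio
BG2n/(FG2n + FBG2n) ‰	BG2n	FG2n+FBG2n	permille
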