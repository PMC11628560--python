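name	class	start	end	sub_region
D-loop	D-loop	16024	576
7S	D-loop	16106	191	7S
non-7S-a	D-loop	16024	16105	non-7S
non-7S-b	D-loop	192	576	non-7S
RNR1	rRNA	648	1601
RNR2	rRNA	1671	3229
TRNF	tRNA	577	647
TRNV	tRNA	1602	1670
TRNL1	tRNA	3230	3304
TRNI	tRNA	4263	4331
TRNQ	tRNA	4329	4400
TRNM	tRNA	4402	4469
TRNW	tRNA	5512	5579
TRNA	tRNA	5587	5655
TRNN	tRNA	5657	5729
TRNC	tRNA	5761	5826
TRNY	tRNA	5826	5891
TRNS1	tRNA	7446	7514
TRND	tRNA	7518	7585
TRNK	tRNA	8295	8364
TRNG	tRNA	9991	10058
TRNR	tRNA	10405	10469
TRNH	tRNA	12138	12206
TRNS2	tRNA	12207	12265
TRNL2	tRNA	12266	12336
TRNE	tRNA	14674	14742
TRNT	tRNA	15888	15953
TRNP	tRNA	15956	16023
ND1	mRNA	3307	4262
ND2	mRNA	4470	5511
CO1	mRNA	5904	7445
CO2	mRNA	7586	8269
ATP8	mRNA	8366	8572
ATP6	mRNA	8527	9207
CO3	mRNA	9207	9990
ND3	mRNA	10059	10404
ND4L	mRNA	10470	10766
ND4	mRNA	10760	12137
ND5	mRNA	12337	14148
ND6	mRNA	14149	14673
CYB	mRNA	14747	15887
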