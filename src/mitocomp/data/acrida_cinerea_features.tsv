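# Acrida cinerea mitogenome organisation (GenBank GU344100), 1-based inclusive coordinates.
# genome_length=15599
name	category	start	end	strand	start_codon	stop_annotation
trnI	tRNA	1	67	Plus	.	.
trnQ	tRNA	68	136	Minus	.	.
trnM	tRNA	140	208	Plus	.	.
nad2	PCG	209	1229	Plus	ATG	T-
trnW	tRNA	1230	1296	Plus	.	.
trnC	tRNA	1289	1352	Minus	.	.
trnY	tRNA	1359	1427	Minus	.	.
cox1	PCG	1420	2959	Plus	AAA	T-
trnL(uur)	tRNA	2960	3024	Plus	.	.
cox2	PCG	3027	3708	Plus	ATG	T-
trnD	tRNA	3709	3773	Plus	.	.
trnK	tRNA	3776	3846	Plus	.	.
atp8	PCG	3861	4022	Plus	ATA	TAA
atp6	PCG	4016	4693	Plus	ATG	TAA
cox3	PCG	4697	5488	Plus	ATG	TAA
trnG	tRNA	5491	5557	Plus	.	.
nad3	PCG	5558	5911	Plus	ATT	TAA
trnA	tRNA	5913	5979	Plus	.	.
trnR	tRNA	5983	6046	Plus	.	.
trnN	tRNA	6049	6114	Plus	.	.
trnS(agn)	tRNA	6115	6181	Plus	.	.
trnE	tRNA	6182	6247	Plus	.	.
trnF	tRNA	6249	6313	Minus	.	.
nad5	PCG	6314	8040	Minus	GCU	TA-
trnH	tRNA	8047	8112	Minus	.	.
nad4	PCG	8116	9450	Minus	ATG	TAG
nad4L	PCG	9444	9737	Minus	ATG	TAA
trnT	tRNA	9738	9806	Plus	.	.
trnP	tRNA	9807	9871	Minus	.	.
nad6	PCG	9872	10393	Plus	ATG	TAA
cob	PCG	10400	11539	Plus	ATG	TAA
trnS(ucn)	tRNA	11542	11611	Plus	.	.
nad1	PCG	11633	12577	Minus	ATG	TAG
trnL(cun)	tRNA	12581	12645	Minus	.	.
rrnL	rRNA	12646	13961	Minus	.	.
trnV	tRNA	13962	14033	Minus	.	.
rrnS	rRNA	14034	14815	Minus	.	.
A+T-rich region	control	14816	15599	Minus	.	.
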