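taxon	accession	fwd_variant	rev_variant	pct_similarity	site_flag	span
Alicyclobacillus acidocaldarius subsp. acidocaldarius	AJ496806	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	87	+	902-1363
Amphibacillus sediminis	AB243866	CTGAAACTCAAA[A]GAATTGACG	AATACGTTCCCGGG[T]CTT	96	-	928-1386
Amphibacillus xylanus	D82065	CTGAAACTCAAA[A]GAATTGACG	AATACGTTCCCGGG[T]CTT	94	-	948-1406
Aneurinibacillus aneurinilyticus	X94194	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGG[T]CTT	91	-	903-1369
Brevibacillus brevis	AB271756	[G]TGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	91	+	896-1356
Gracilibacillus halotolerans	AF036922	CTGAAACTCAAA[A]GAATTGACG	AATACGTTCCCGGGCCTT	94	+	934-1394
Paenibacillus polymyxa	D16276	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGG[T]CTT	90	-	913-1375
Virgibacillus pantothenticus	D16275	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGG[T]CTT	95	-	919-1375
Virgibacillus proomii	AJ012667	CTGAAACTCAAA[A]GAATTGACG	AATACGTTCCCGGG[T]CTT	95	-	916-1372
Virgibacillus koreensis	AY616012	CTGAAACTCAAA[A]GAATTGACG	AATACGTTCCCGGGCCTT	97	+	926-1386
Geobacillus stearothermophilus	AB021196	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	93	+	912-1376
Geobacillus debilis	AJ564616	CTGAAACTCAAAGGAATTGACG	AATACGTTC[T]CGGGCCTT	91	-	936-1398
Geobacillus tepidamans	AY563003	[G]TGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	95	+	872-1334
Filobacillus milosensis	AJ238042	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	94	+	915-1375
Jeotgalibacillus alimentarius	AF281158	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	96	+	911-1373
Ureibacillus thermosphaericus	AB101594	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	92	+	931-1392
Ureibacillus suwonensis	AY850379	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	92	-	918-1379
Lysinibacillus sphaericus	AJ310084	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	93	+	920-1382
Lysinibacillus boronitolerans	AB199591	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	93	+	898-1360
Terribacillus saccharophilus	AB243845	CTGAAACTCAAA[A]GAATTGACG	AATACGTTCCCGGGCCTT	94	+	922-1382
Bacillus marisflavi	AF483624	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	100	+	909-1371
Bacillus aquimaris	AF483625	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	99	+	910-1372
Bacillus vietnamensis	AB099708	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	98	+	903-1365
Bacillus mycoides	AB021192	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	97	+	907-1367
Bacillus thuringiensis	D16281	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	97	+	911-1371
Bacillus pseudomycoides	AF013121	CTGAAACTCAAAGGA[T]TTGACG	AATACGTTCCCGGGCCTT	95	+	932-1392
Bacillus megaterium	D16273	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	98	+	910-1372
Bacillus beijingensis	EF371374	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGG[T]CTT	96	-	929-1387
Bacillus psychrodurans	AJ277984	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	95	-	918-1380
Bacillus flexus	AB021185	CTGAAACTCAAAGGAATTGACG	AATACGTTCCCGGGCCTT	98	+	923-1385
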