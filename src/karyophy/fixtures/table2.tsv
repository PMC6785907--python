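# Chromosome-painting homology table: 24 Hylaeamys megacephalus (HME) whole-chromosome
# probes hybridized onto 14 sigmodontine karyotypes.  Cell grammar: comma-separated
# signals; each signal = target chromosome [arm] [region [and region]] [(ts)].
# p/q = short/long arm; prox/int/dist = region on the arm; (ts) = probe paints two
# separated segments at that location.  The HME reference column is implicit
# (probe N paints HME chromosome N; composite probes paint both their chromosomes).
#
# Transcription notes:
#  - The printed per-column totals (checksum row below) count every painted segment,
#    so a (ts) signal and a signal spanning disjoint prox+dist regions count twice.
#  - Row 3: the source table runs cells together; resolved as NSP-A '3', NSP-B '2p'
#    (NSP-B is the most fusion-rich karyotype).  All column checksums verify.
#  - AMO row X: printed "X (Xq)" (whole-probe signal confined to Xq); normalized to "Xq".
#  - ASP (ts) marks on rows (9,10), (16,17) and 18 are inferred: the printed total
#    (45) requires three more segments than the legible marks provide, and ASP's 3q
#    carries ten interleaved signals.
probe	CLA	TNI	AMO	ASP	NLA	OCA-PA	OCA-RJ	NSP-A	NSP-B	NSP-C	NSP-D	NPA	NSP-E	NAM
1	2q, 20	4, 8	1q dist., 4q	1q int., 2q dist.	5q dist., 7	13, 16, 29	13, 17, 28	6, 8	2p, 4q	6, 8	6, 8	6, 8	6, 8	6, 8
2	10, 18, 19	7, 12	1q int., 7q	1p dist., 2q int.	9q int., 13	4	1p, 4	2	3q	2	2	2	2	2
3	1q int., 3p	1 int. and dist.	2q	2p dist.	3q dist.	11q	3	3	2p	3	3	3	3	3
4	5, 13	13, 15	1p prox., 5p dist.	2q prox. and int., 3q int.	1q prox., 10q prox., 11q dist.	2	2	1q dist.	1q dist.	1q dist.	1q dist.	1q dist.	1q dist.	1q dist.
5	1p dist., 1q prox., 8	2 dist., 5 prox., 6 prox.	3q int., 6p int., 10	1p int. and prox., 3q int. (ts)	6q dist., 12q int., 14q dist.	3q dist., 15, 27	3q dist., 15, 27	19, 22, 24, 26p	3p dist., 21, 22, 24	15q dist., 19, 24	15q dist., 19, 23	19, 26	9, 17	9, 28, 31
6	4q dist.	3 prox. and int.	2p	2p int.	2q int.	9, 25, 26	9, 16	5q prox., 18	5q prox., 8	5q prox., 18	5q prox., 18	5q prox., 18	5q prox., 19	5q prox., 18
7	3q int.	18	5q prox., 8q	1p int., 3q int.	1q int., 4q prox.	7	7	7, 9q int.	3p int., 5p	7, 9q int.	7, 9q int.	7, 9q int.	7, 10q int.	7, 10q int.
8	4q prox., 7	6 dist.	3p	3q prox.	1q int.	5	5	12, 13	6, 15	12, 13	12, 13	12, 13	12, 16	12, 16
(9,10)	2p dist., 3q dist.	2 prox., 5 dist.	5q, 9p	1q int., 3q int. (ts)	1q dist., 6q prox.	3q prox., 12	3q prox., 12	9q (ts), 10	1p, 3p int. (ts)	9q (ts), 10	9q (ts), 10	9q (ts), 10	10q (ts), 14	10q (ts), 14
11	1q prox., 6	9 dist., 10 prox.	1p int., 6q dist.	2q int., 3q dist.	10q int., 12q dist.	6q dist., 8 dist.	6q dist., 8q dist.	20, 23p	11, 26	20, 22	20, 22q	14, 25p	24, 25	22, 23
12	2p prox.	16	1q int.	2q int.	5q prox.	14	14	4q prox.	4q prox.	4q prox.	4q prox.	4q prox.	4q prox.	4q prox.
(13,22)	1q (ts), 9	9 prox., 11 int. and dist., 21	3q prox., 4p dist., 6q prox.	1q int., 3q int. (ts)	4q dist., 12q prox., 14q prox.	10q dist., 18q prox., 22	10q dist., 19q prox., 22	1q int., 26q, 27p	1q int., 19, 23	1q int., 21, 28p	1q int., 21, 28p	1q int., 20, 21	1q int., 21, 23	1q int., 19, 21
14	1p int., 21	17 prox., 24	6p prox., 8p int.	1p int., 3q int.	2q int., 15q int.	3q int., 30	3q int., 29	23q, 25p prox.	20, 25	25q, 26p prox.	24q, 25p prox.	16, 24p prox.	26, 28	24, 26
15	12	19	9q	1q dist.	8q dist.	11	11	15	9	17	17	15	15	15
(16,17)	1q prox., 11q dist.	10 dist., 22	1p dist., 3q dist.	2p prox., 2q int., 3q int. (ts)	2q prox., 10q dist.	19, 20	20, 24	4q dist., 16	4q dist., 10	4q dist., 16	4q dist., 16	4q dist., 25q	4q dist., 22	4q dist., 20
18	16	1 prox., 23	1q prox., 5p prox.	2p int., 2q int., 3q int. (ts)	3q prox., 9q prox.	21	21	7	7	15q prox.	15q prox.	17	27	25
19	1p int., 3q prox.	17 dist.	8p dist., 8q prox.	1p int. (ts)	15q prox. and dist.	6q int., 28	6q int., 26	14, 25p dist.	18	14, 26p dist.	14, 25p dist.	24p dist., 24q	18	17
20	1q dist.	11 prox.	4q prox.	1q prox. and int.	4q int.	10q prox.	10q prox.	1q prox.	1q prox.	1q prox.	1q prox.	1q prox.	1q prox.	1q prox.
21	4p, 4q int.	3 dist.	2p dist.	2p int.	2q dist.	18q dist.	19q dist.	5q dist.	5q dist.	5q dist.	5q dist.	5q dist.	5q dist.	5q dist.
23	15	20	7p	1p int.	8q prox.	6q prox., 23	6q prox., 23	21, 25q	14, 16	23, 26q	25q, 26q	23	13, 20	13, 29
24	14	14	6p dist.	3q int. (ts)	9q dist.	17	18	11	12	11	11	11	11	11
25	17	1 prox.	2p prox.	2p int., 3q int.	3q int., 11q prox.	24	25	28	13	27	27	27	29	27
26	22	25	11	4	16	8q prox.	8q prox.	27q	17	28q	28q	22	30	30
X	X	X	Xq	X	X	Xq	Xq	Xq	X	Xq	Xq	X	Xq	Xq
Total	40	36	38	45	40	38	38	40	39	39	39	37	37	38
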