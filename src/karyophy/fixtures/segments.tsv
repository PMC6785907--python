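# Syntenic sub-block registry for the seven Neacomys karyotypes (registry version 1).
# Each row is one conserved sub-block of an HME probe block; the taxon columns give
# the target chromosome carrying that sub-block.  Sub-block identities are pinned by
# co-painting context wherever the homology table forces the match (e.g. 6a lies with
# 21, 7b sits inside the two-segment (9,10) signal, the 19/14/x complex, (13,22)/26,
# 12/(16,17), 20/(13,22)/4, 11/(16,17) in NPA, 1/12/(16,17) in NSP-B); the remaining
# assignments maximize homology, i.e. minimize the rearrangement events they imply.
# Composite-probe sub-blocks are labelled a/b/c because painting cannot tell which of
# the two source chromosomes a given segment derives from.
# X is carried for completeness; fusion/fission tallies exclude it.
segment	probe	NSP-A	NSP-B	NSP-C	NSP-D	NPA	NSP-E	NAM
1a	1	6	2	6	6	6	6	6
1b	1	8	4	8	8	8	8	8
2	2	2	3	2	2	2	2	2
3	3	3	2	3	3	3	3	3
4	4	1	1	1	1	1	1	1
5a	5	19	21	19	19	26	17	9
5b	5	22	22	15	15	19	9	28
5c	5	24	24	24	23	26	17	31
5d	5	26	3	15	15	19	9	28
6a	6	5	5	5	5	5	5	5
6b	6	18	8	18	18	18	19	18
7a	7	7	5	7	7	7	7	7
7b	7	9	3	9	9	9	10	10
8a	8	12	6	12	12	12	12	12
8b	8	13	15	13	13	13	16	16
(9,10)a	(9,10)	9	3	9	9	9	10	10
(9,10)b	(9,10)	10	1	10	10	10	14	14
11a	11	20	11	20	20	14	24	22
11b	11	23	26	22	22	25	25	23
12	12	4	4	4	4	4	4	4
(13,22)a	(13,22)	1	1	1	1	1	1	1
(13,22)b	(13,22)	26	19	21	21	20	21	19
(13,22)c	(13,22)	27	23	28	28	21	23	21
14a	14	23	20	25	24	16	26	24
14b	14	25	25	26	25	24	28	26
15	15	15	9	17	17	15	15	15
(16,17)a	(16,17)	4	4	4	4	4	4	4
(16,17)b	(16,17)	16	10	16	16	25	22	20
18	18	7	7	15	15	17	27	25
19a	19	14	18	14	14	24	18	17
19b	19	25	18	26	25	24	18	17
20	20	1	1	1	1	1	1	1
21	21	5	5	5	5	5	5	5
23a	23	21	14	23	26	23	13	13
23b	23	25	16	26	25	23	20	29
24	24	11	12	11	11	11	11	11
25	25	28	13	27	27	27	29	27
26	26	27	17	28	28	22	30	30
X	X	X	X	X	X	X	X	X
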