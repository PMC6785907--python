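# Karyotype descriptors for the painted karyotypes, transcribed from the study's
# karyotype descriptions.  Only facts the text states (or that follow directly from
# arm-resolved signals) are recorded; morphologies of pairs never mentioned and not
# arm-resolved are left unlisted.  Bi-armed pairs known only from two-arm painted
# content are recorded as submetacentric by convention (downstream comparisons only
# distinguish acrocentric vs bi-armed).
# columns: taxon, 2n, FN, morphologies (chrom:class;...), ch_blocks (chrom+arm;...)
# classes: a=acrocentric, m=metacentric, sm=submetacentric
taxon	diploid_number	fundamental_number	morphologies	ch_blocks
NSP-A	58	68	23:sm;25:sm;26:sm;27:sm;X:sm	Xp
NSP-B	54	66	1:sm;3:sm;5:sm;X:a
NSP-C	58	64	22:a;23:a;24:a;26:sm;28:sm;X:sm	Xp
NSP-D	58	70	22:m;23:m;26:m;25:sm;28:sm;X:sm	22p;23p;26p;Xp
NPA	56	64	24:sm;25:sm;X:a
NSP-E	62	60	1:a;2:a;3:a;4:a;5:a;6:a;7:a;8:a;9:a;10:a;11:a;12:a;13:a;14:a;15:a;16:a;17:a;18:a;19:a;20:a;21:a;22:a;23:a;24:a;25:a;26:a;27:a;28:a;29:a;30:a;X:a
NAM	64	68	X:sm	Xp
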