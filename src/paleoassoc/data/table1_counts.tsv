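kind	group	category	variant	coastal	terrestrial
taxon	Abelisauridae	1	I	1	26
taxon	Abelisauridae	1	II	1	12
taxon	Abelisauridae	1	III	1	24
taxon	Abelisauridae	1	IV	1	11
taxon	Abelisauridae	2	I	2	37
taxon	Abelisauridae	2	II	2	13
taxon	Abelisauridae	2	III	1	29
taxon	Abelisauridae	2	IV	1	8
taxon	Abelisauridae	unspecified	I	0	0
taxon	Abelisauridae	unspecified	II	0	0
taxon	Abelisauridae	unspecified	III	0	0
taxon	Abelisauridae	unspecified	IV	0	0
taxon	Carcharodontosauridae	1	I	0	15
taxon	Carcharodontosauridae	1	II	0	11
taxon	Carcharodontosauridae	1	III	0	15
taxon	Carcharodontosauridae	1	IV	0	10
taxon	Carcharodontosauridae	2	I	9	41
taxon	Carcharodontosauridae	2	II	6	20
taxon	Carcharodontosauridae	2	III	5	27
taxon	Carcharodontosauridae	2	IV	5	13
taxon	Carcharodontosauridae	unspecified	I	1	0
taxon	Carcharodontosauridae	unspecified	II	1	0
taxon	Carcharodontosauridae	unspecified	III	0	0
taxon	Carcharodontosauridae	unspecified	IV	0	0
taxon	Spinosauridae	1	I	6	12
taxon	Spinosauridae	1	II	3	10
taxon	Spinosauridae	1	III	5	10
taxon	Spinosauridae	1	IV	3	8
taxon	Spinosauridae	2	I	8	52
taxon	Spinosauridae	2	II	7	20
taxon	Spinosauridae	2	III	4	32
taxon	Spinosauridae	2	IV	4	13
taxon	Spinosauridae	unspecified	I	2	1
taxon	Spinosauridae	unspecified	II	1	1
taxon	Spinosauridae	unspecified	III	0	0
taxon	Spinosauridae	unspecified	IV	0	0
epoch	Early Cretaceous	-	I	14	77
epoch	Early Cretaceous	-	II	9	34
epoch	Early Cretaceous	-	III	10	54
epoch	Early Cretaceous	-	IV	8	27
epoch	Late Cretaceous	-	I	8	88
epoch	Late Cretaceous	-	II	4	36
epoch	Late Cretaceous	-	III	3	74
epoch	Late Cretaceous	-	IV	3	28
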