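Variant Start	Variant End	Length	Amino Acid Change	CDS Position	Change	Codon Change	Polymorphism Type
1680	1680	1			C→T		SNP (transition)
2209	2208	0			-TTC		Deletion
2630	2630	1			A→T		SNP (transversion)
2786	2786	1		30	C→T	ACC→ACT	SNP (transition)
3200	3200	1		444	C→T	ATC→ATT	SNP (transition)
3296	3296	1		540	G→A	CCG→CCA	SNP (transition)
3323	3323	1		567	A→G	ACA→ACG	SNP (transition)
3668	3668	1		912	T→C	TAT→TAC	SNP (transition)
3688	3688	1	T→M	932	C→T	ACA→ATA	SNP (transition)
4605	4605	1		684	T→C	CTT→CTC	SNP (transition)
4674	4674	1		753	C→T	CTC→CTT	SNP (transition)
4770	4770	1		849	C→T	GCC→GCT	SNP (transition)
5178	5178	1			T→C		SNP (transition)
5409	5409	1		66	T→C	TTT→TTC	SNP (transition)
5541	5541	1		198	T→C	ATT→ATC	SNP (transition)
5652	5652	1		309	A→G	TGA→TGG	SNP (transition)
6312	6312	1		969	G→A	TGG→TGA	SNP (transition)
6360	6360	1		1017	C→T	CTC→CTT	SNP (transition)
6522	6522	1		1179	T→C	TTT→TTC	SNP (transition)
7043	7043	1		13	C→T	CTA→TTA	SNP (transition)
7453	7453	1		423	A→G	CGA→CGG	SNP (transition)
7489	7489	1		459	A→G	CTA→CTG	SNP (transition)
7834	7834	1		51	T→C	ATT→ATC	SNP (transition)
7909	7909	1		126	T→C	GTT→GTC	SNP (transition)
8013	8013	1		69	T→C	ATT→ATC	SNP (transition)
8284	8284	1	I→V	340	A→G	ATT→GTT	SNP (transition)
8651	8651	1		27	T→C	CAT→CAC	SNP (transition)
8702	8702	1		78	C→T	CTC→CTT	SNP (transition)
8942	8942	1		318	G→A	CTG→CTA	SNP (transition)
9356	9356	1		732	C→T	TTC→TTT	SNP (transition)
10013	10013	1		120	T→C	ATT→ATC	SNP (transition)
10019	10019	1		126	T→C	ATT→ATC	SNP (transition)
10036	10036	1	V→A	143	T→C	GTC→GCC	SNP (transition)
10082	10082	1		189	T→C	ATT→ATC	SNP (transition)
10112	10112	1		219	A→G	GTA→GTG	SNP (transition)
10519	10519	1		336	C→T	GCC→GCT	SNP (transition)
10591	10591	1		408	A→G	TGA→TGG	SNP (transition)
10690	10690	1	N→K	507	C→A	AAC→AAA	SNP (transversion)
11528	11528	1		1345	T→C	TTA→CTA	SNP (transition)
11734	11734	1			(A)5→(A)6		Insertion (tandem repeat)
12517	12517	1		759	A→G	GTA→GTG	SNP (transition)
13366	13366	1		1608	G→A	TCG→TCA	SNP (transition)
13945	13945	1			G→A		SNP (transition)
14005	14005	1			A→G		SNP (transition)
14466	14466	1	I→V	304	A→G	ATC→GTC	SNP (transition)
14637	14637	1	D→N	475	G→A	GAC→AAC	SNP (transition)
14703	14703	1	F→L	541	T→C	TTC→CTC	SNP (transition)
14837	14837	1		675	C→T	ACC→ACT	SNP (transition)
14954	14954	1		792	T→C	ACT→ACC	SNP (transition)
15356	15356	1			(A)5→(A)6		Insertion (tandem repeat)
15515	15515	1			T→C		SNP (transition)
15544	15544	1			T→C		SNP (transition)
15632	15632	1			T→A		SNP (transversion)
15634	15634	1			G→A		SNP (transition)
15674	15674	1			T→C		SNP (transition)
15685	15685	1			G→A		SNP (transition)
15692	15692	1			C→T		SNP (transition)
15755	15755	1			C→T		SNP (transition)
15766	15766	1			C→T		SNP (transition)
15813	15813	1			G→A		SNP (transition)
15815	15815	1			A→G		SNP (transition)
15817	> 15817	> 1			GT→A		Deletion
15907	15907	1			+A		Insertion
16376	16439	64			(ACACGTATACACGTATACACGTATACACGTAT)8→(ACACGTATACACGTATACACGTATACACGTAT)10		Insertion (tandem repeat)
16504	16504	1			A→C		SNP (transversion)
16507	16509	3			+ACC		Insertion
16527	16528	2			GC→CG		Substitution
16689	16689	1			A→G		SNP (transition)
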