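Variant Start	Variant End	Length	Amino Acid Change	CDS Position	Change	Codon Change	Polymorphism Type
1033	1033	1			A→G		SNP (transition)
3107	3107	1		351	G→A	CTG→CTA	SNP (transition)
3296	3296	1		540	A→G	CCA→CCG	SNP (transition)
3347	3347	1		591	A→C	CCA→CCC	SNP (transversion)
4047	4047	1		126	C→A	CCC→CCA	SNP (transversion)
4770	4770	1		849	T→C	GCT→GCC	SNP (transition)
4810	4810	1	V→I	889	G→A	GTC→ATC	SNP (transition)
5541	5541	1		198	C→T	ATC→ATT	SNP (transition)
6522	6522	1		1179	C→T	TTC→TTT	SNP (transition)
6804	6804	1		1461	T→C	CTT→CTC	SNP (transition)
7043	7043	1		13	T→C	TTA→CTA	SNP (transition)
7834	7834	1		51	C→T	ATC→ATT	SNP (transition)
7909	7909	1		126	C→T	GTC→GTT	SNP (transition)
8284	8284	1	V→I	340	G→A	GTT→ATT	SNP (transition)
8702	8702	1		78	T→C	CTT→CTC	SNP (transition)
9959	9959	1		66	T→C	TAT→TAC	SNP (transition)
10013	10013	1		120	C→T	ATC→ATT	SNP (transition)
10019	10019	1		126	C→T	ATC→ATT	SNP (transition)
10112	10112	1		219	G→A	GTG→GTA	SNP (transition)
10288	10288	1		105	T→C	AGT→AGC	SNP (transition)
11528	11528	1		1345	C→T	CTA→TTA	SNP (transition)
12517	12517	1		759	G→A	GTG→GTA	SNP (transition)
13764	13764	1	N→Y	325	T→A	AAT→TAT	SNP (transversion)
14687	14687	1		525	A→G	CTA→CTG	SNP (transition)
14703	14703	1	L→F	541	C→T	CTC→TTC	SNP (transition)
14837	14837	1		675	T→C	ACT→ACC	SNP (transition)
14954	14954	1		792	C→T	ACC→ACT	SNP (transition)
15544	15544	1			C→T		SNP (transition)
15561	15561	1			T→C		SNP (transition)
15618	15618	1			C→T		SNP (transition)
15634	15634	1			A→G		SNP (transition)
15692	15692	1			T→C		SNP (transition)
15702	15702	1			A→G		SNP (transition)
16136	16136	1			T→C		SNP (transition)
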