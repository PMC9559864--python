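# Reconstructed beta-thalassemia hotspot coordinates (hg19); positions
# follow HBB cDNA-to-genome conventions, alleles VCF-style left-anchored.
name	chrom	pos	ref	alt
-29(A>G)	chr11	5248330	A	G
-28(A>G)	chr11	5248329	A	G
CD17(A>T)	chr11	5248251	A	T
CD26(G>A)	chr11	5248224	G	A
IVS-1-1(G>T)	chr11	5248159	G	T
IVS-1-5(G>C)	chr11	5248155	G	C
CD27-28(+T)	chr11	5248029	C	CT
CD41-42(-CTTT)	chr11	5247994	TCTTT	T
CD43(G>T)	chr11	5247990	G	T
CD71-72(+A)	chr11	5247904	C	CA
IVS-2-654(C>T)	chr11	5246957	C	T
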