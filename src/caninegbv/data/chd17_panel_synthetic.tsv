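# Bundled 17-marker CHD panel (SYNTHETIC stand-in).
# Contexts for TiHo1/TiHo18/TiHo19/TiHo35 and the CHD-associated alleles of
# TiHo12 (T), TiHo25 (G), TiHo26 (C) are the published values; all other
# contexts/alleles and ALL numerical weights are synthetic placeholders,
# since the patented weight table is not redistributable here.
marker_id	wild_allele	mutant_allele	wild_context	mutant_context	w_hom	w_het
TiHo1	A	G	CAAGAGT[A]TCCAGTTCC	CAAGAGT[G]TCCAGTTCC	0.62	0.21
TiHo2	A	G	TTCCGTGT[A]CGTATCGGCGC	TTCCGTGT[G]CGTATCGGCGC	0.34	0.12
TiHo4	T	C	TGATACGAGAC[T]TAGGAGCGTGTG	TGATACGAGAC[C]TAGGAGCGTGTG	0.55	0.3
TiHo6	T	G	TTTGTCTAA[T]TGGAGGGTG	TTTGTCTAA[G]TGGAGGGTG	0.18	0.05
TiHo9	C	A	CCTGCAAATAG[C]CCACGAGC	CCTGCAAATAG[A]CCACGAGC	0.47	0.16
TiHo12	C	T	GCCGCCAGATG[C]TAATTAGGTC	GCCGCCAGATG[T]TAATTAGGTC	0.73	0.28
TiHo14	T	A	CTGCTTAA[T]TTACTGTTCA	CTGCTTAA[A]TTACTGTTCA	0.26	0.09
TiHo16	T	A	AATAGCCC[T]CCGTTTAAGGCG	AATAGCCC[A]CCGTTTAAGGCG	0.41	0.22
TiHo18	T	G	TTCCCTCCCTGTG[T]TTCCTTCCA	TTCCCTCCCTGTG[G]TTCCTTCCA	0.58	0.31
TiHo19	C	T	CTAAAATCTGA[C]ATAGCCAAAG	CTAAAATCTGA[T]ATAGCCAAAG	0.39	0.14
TiHo21	T	A	AGCTATGAG[T]ATGAACAGTTG	AGCTATGAG[A]ATGAACAGTTG	0.22	0.08
TiHo25	A	G	CGCCAAGGTATG[A]TGACATTG	CGCCAAGGTATG[G]TGACATTG	0.66	0.35
TiHo26	T	C	AATAAGCG[T]GTGTTAAC	AATAAGCG[C]GTGTTAAC	0.5	0.19
TiHo29	T	G	ATACTCGTGTT[T]TGTCGACGAG	ATACTCGTGTT[G]TGTCGACGAG	0.29	0.11
TiHo31	A	T	GTGCTCGT[A]ATCCCTTCGC	GTGCTCGT[T]ATCCCTTCGC	0.44	0.24
TiHo35	G	C	TTAGAAAGGT[G]ACTTTCCAGG	TTAGAAAGGT[C]ACTTTCCAGG	0.61	0.27
TiHo37	C	G	CGGAGCCTGG[C]CCATTCAGC	CGGAGCCTGG[G]CCATTCAGC	0.37	0.13
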