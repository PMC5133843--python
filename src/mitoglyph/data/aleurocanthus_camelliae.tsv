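#genome_length=15188
# Annotation of the Aleurocanthus camelliae mitogenome (GenBank KU761949),
# transcribed from the published annotation table. Coordinates are 1-based
# inclusive. Strand assignments are reconstructed from the ancestral insect
# arrangement plus the rearrangement events described for this genome
# (the published table marks strand typographically, which plain text loses);
# cross-check against the accession when available.
# Note: the published Size cell for trnY reads 60, but its coordinates
# 15063-15124 give 62 bp; lengths here derive from coordinates.
# The published trnG row (12161-12222, size 63) and cox3 row (12223-13009,
# size 786) are off by one against each other; the boundary is placed at
# 12223/12224 here, which makes every published total (gene sizes, inc
# column, PCG bp, codon count) internally consistent.
name	start	end	strand	class	start_codon	stop_codon	anticodon
cox1	1	1539	+	PCG	ATG	TAA	-
trnL2	1542	1606	+	tRNA	-	-	TAA
cox2	1607	2270	+	PCG	ATT	T-	-
trnK	2271	2340	+	tRNA	-	-	CTT
trnD	2347	2408	+	tRNA	-	-	GTC
atp8	2418	2564	+	PCG	ATA	TAA	-
atp6	2558	3208	+	PCG	ATT	TAG	-
trnE	3233	3293	+	tRNA	-	-	TTC
trnF	3301	3363	-	tRNA	-	-	GAA
nad5	3364	5023	-	PCG	ATA	T-	-
trnH	5024	5084	-	tRNA	-	-	GTG
nad4	5086	6366	-	PCG	ATA	TAG	-
nad4L	6363	6659	-	PCG	ATG	TAA	-
trnT	6661	6724	+	tRNA	-	-	TGT
trnP	6723	6784	-	tRNA	-	-	TGG
nad6	6816	7250	+	PCG	ATA	TAA	-
cob	7250	8383	+	PCG	ATG	TAA	-
trnS2	8384	8439	+	tRNA	-	-	TGA
nad1	8450	9359	-	PCG	ATT	T-	-
trnL1	9360	9422	-	tRNA	-	-	TAG
rrnL	9423	10612	-	rRNA	-	-	-
rrnS	10707	11435	-	rRNA	-	-	-
trnN	11483	11548	+	tRNA	-	-	ATT
trnQ	11553	11623	-	tRNA	-	-	TTG
trnV	11617	11680	-	tRNA	-	-	TAC
trnR	11678	11742	-	tRNA	-	-	TCG
trnA	11744	11805	-	tRNA	-	-	TGC
nad3	11806	12159	-	PCG	ATT	TAA	-
trnG	12161	12223	-	tRNA	-	-	TCC
cox3	12224	13009	-	PCG	ATG	TAA	-
trnS1	13025	13086	+	tRNA	-	-	TCT
CR	13087	13961	+	control	-	-	-
trnM	13962	14028	+	tRNA	-	-	CAT
nad2	14029	15003	+	PCG	ATA	TAA	-
trnW	15002	15064	+	tRNA	-	-	TCA
trnY	15063	15124	-	tRNA	-	-	GTA
trnC	15125	15187	-	tRNA	-	-	GCA
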