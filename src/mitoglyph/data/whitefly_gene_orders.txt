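# Mitochondrial gene orders for the family Aleyrodidae and the hypothetical
# ancestral insect, as signed circular permutations anchored at cox1 (sign =
# strand relative to cox1). Control region and non-coding spans are omitted.
#
# Provenance: A_camelliae is taken from its published annotation table; the
# ancestral insect order is the standard Drosophila-like arrangement; the
# remaining whitefly orders are reconstructed from the published comparative
# narrative (shared gene blocks, the cox3-trnG-nad3(-trnA-trnR(-trnN))
# inverse transposition per lineage, the trnS1/trnE/trnF rearrangement steps,
# and the per-genome tRNA absences). Orders other than A_camelliae and the
# ancestor are approximate where the narrative does not pin them and should
# not be treated as authoritative transcriptions of the source genomes.
ancestral: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
A_camelliae: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-rrnS,trnN,-trnQ,-trnV,-trnR,-trnA,-nad3,-trnG,-cox3,trnS1,trnM,nad2,trnW,-trnY,-trnC
T_acaciae: cox1,trnL2,cox2,trnK,-trnD,atp8,atp6,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-rrnS,-trnQ,-trnV,-nad3,-trnG,-cox3,-trnA,trnR,trnM,nad2,trnW,-trnY,-trnC
B_tabaci: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,-trnS1,-trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnN,-trnR,-trnA,-nad3,-trnG,-cox3,trnI,-trnQ,trnM,nad2,trnW,-trnY,-trnC
B_afer: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,-trnS1,-trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnN,-trnR,-trnA,-nad3,-trnG,-cox3,trnI,-trnQ,trnM,nad2,trnW,-trnY,-trnC
A_aceris: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,-trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnR,-trnA,-nad3,-trnG,-cox3,trnN,-trnQ,trnM,nad2,trnW,-trnY,-trnC
N_andropogonis: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,-trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,-nad1,-trnL1,-rrnL,-nad3,-trnG,-cox3,rrnS,trnV,trnM,nad2,trnW,-trnY,-trnC
A_dugesii: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,trnQ,trnI,trnM,nad2,trnW,-trnY,-trnC
T_vaporariorum: cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,trnI,-trnQ,trnM,nad2,trnW,-trnY,-trnC
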