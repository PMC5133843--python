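# Reference protein-coding gene length ranges (bp) for the family
# Aleyrodidae, used by the punctuation/re-annotation audit to flag PCGs
# whose annotated length deviates from the family norm. The cox2 range is
# the published family range; the remaining ranges bracket the
# A. camelliae values by +/-5% as a family-scale default. Editable.
cox1: [1462, 1616]
cox2: [661, 667]
cox3: [747, 825]
nad1: [865, 956]
nad2: [926, 1024]
nad3: [336, 372]
nad4: [1217, 1345]
nad4L: [282, 312]
nad5: [1577, 1743]
nad6: [413, 457]
atp6: [618, 684]
atp8: [140, 154]
cob: [1077, 1191]
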