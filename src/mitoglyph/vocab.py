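"""Controlled gene vocabulary and genetic-code helpers for animal mitogenomes.

The canonical animal mitochondrial complement is 37 genes: 13 protein-coding
genes, 2 rRNAs and 22 tRNAs.  tRNA names use single amino-acid letters with
the usual S1/S2 (AGN/UCN) and L1/L2 (CUN/UUR) disambiguation.  The genetic
code throughout is the invertebrate mitochondrial code (NCBI table 5), under
which AGA/AGG encode Ser, AUA encodes Met and UGA encodes Trp.

The DNA alphabet (T, not U) is used internally everywhere; codons and
anticodons are accepted in either spelling and normalised on entry.
"""

from __future__ import annotations

from Bio.Data import CodonTable

PCGS = (
    "cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4L",
    "nad5", "nad6", "atp6", "atp8", "cob",
)
RRNAS = ("rrnS", "rrnL")
TRNAS = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)
#: The 37-gene canonical animal mitochondrial complement.
CANONICAL_37 = frozenset(PCGS) | frozenset(RRNAS) | frozenset(TRNAS)

#: Non-gene feature names permitted in annotations.
NONGENE_NAMES = ("CR", "NCR")

VALID_CLASSES = ("PCG", "tRNA", "rRNA", "control", "noncoding")

CLASS_OF = {g: "PCG" for g in PCGS}
CLASS_OF.update({g: "rRNA" for g in RRNAS})
CLASS_OF.update({g: "tRNA" for g in TRNAS})
CLASS_OF["CR"] = "control"
CLASS_OF["NCR"] = "noncoding"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ambiguity codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_codon(codon: str) -> str:
    """Upper-case a codon/anticodon and convert RNA spelling (U) to DNA (T)."""
    return codon.strip().upper().replace("U", "T")


def to_rna(codon: str) -> str:
    """DNA codon spelled as RNA, as codon-usage tables conventionally print."""
    return codon.upper().replace("T", "U")


_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: codon (DNA) -> one-letter amino acid; stops map to "*".
CODON_TO_AA = dict(_TABLE5.forward_table)
for _stop in _TABLE5.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = tuple(_TABLE5.stop_codons)  # ("TAA", "TAG") under table 5
ALL_CODONS = tuple(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)


def amino_acid_families() -> dict[str, tuple[str, ...]]:
    """Synonymous codon families keyed by amino-acid letter ("*" = stops)."""
    fam: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        fam.setdefault(CODON_TO_AA[codon], []).append(codon)
    return {aa: tuple(codons) for aa, codons in fam.items()}


def codon_box_families() -> dict[str, tuple[str, ...]]:
    """Synonymous families split by the first two codon positions.

    Under this convention six-fold (Leu) and eight-fold (Ser) amino acids
    fall apart into their codon boxes (e.g. Leu -> UUR + CUN), which is how
    some published codon-usage tables normalise RSCU.
    """
    fam: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        key = CODON_TO_AA[codon] + "/" + codon[:2]
        fam.setdefault(key, []).append(codon)
    return {k: tuple(v) for k, v in fam.items()}


def trna_name_for_codon(codon: str) -> str | None:
    """Map a codon to the tRNA gene that decodes its family.

    Ser and Leu are resolved to S1/S2 and L1/L2 by codon box (S1 = AGN,
    S2 = UCN, L1 = CUN, L2 = UUR); every other amino acid maps to its
    single-letter tRNA name.  Stop codons return None.
    """
    codon = normalize_codon(codon)
    aa = CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        return None
    if aa == "S":
        return "trnS1" if codon.startswith("AG") else "trnS2"
    if aa == "L":
        return "trnL1" if codon.startswith("CT") else "trnL2"
    return "trn" + aa


def identity_from_anticodon(anticodon: str) -> str:
    """tRNA gene name implied by an anticodon (read 5'->3', DNA alphabet).

    The decoded codon is the reverse complement of the anticodon
    (e.g. CAT -> ATG -> trnM, TGA -> TCA -> trnS2).  Anticodons whose codon
    is a stop or invalid return "unknown".
    """
    anticodon = normalize_codon(anticodon)
    if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
        return "unknown"
    name = trna_name_for_codon(revcomp(anticodon))
    return name if name is not None else "unknown"


#: Feature-name synonyms used by the GenBank reader (upper-cased keys).
GENE_SYNONYMS = {
    "COI": "cox1", "CO1": "cox1", "COX1": "cox1", "COXI": "cox1",
    "COII": "cox2", "CO2": "cox2", "COX2": "cox2", "COXII": "cox2",
    "COIII": "cox3", "CO3": "cox3", "COX3": "cox3", "COXIII": "cox3",
    "ND1": "nad1", "NAD1": "nad1", "NADH1": "nad1",
    "ND2": "nad2", "NAD2": "nad2", "NADH2": "nad2",
    "ND3": "nad3", "NAD3": "nad3", "NADH3": "nad3",
    "ND4": "nad4", "NAD4": "nad4", "NADH4": "nad4",
    "ND4L": "nad4L", "NAD4L": "nad4L", "NADH4L": "nad4L",
    "ND5": "nad5", "NAD5": "nad5", "NADH5": "nad5",
    "ND6": "nad6", "NAD6": "nad6", "NADH6": "nad6",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASE 6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASE 8": "atp8",
    "CYTB": "cob", "COB": "cob", "CYB": "cob",
    "12S": "rrnS", "12S RRNA": "rrnS", "S-RRNA": "rrnS", "RRNS": "rrnS",
    "SMALL SUBUNIT RIBOSOMAL RNA": "rrnS",
    "16S": "rrnL", "16S RRNA": "rrnL", "L-RRNA": "rrnL", "RRNL": "rrnL",
    "LARGE SUBUNIT RIBOSOMAL RNA": "rrnL",
    "CONTROL REGION": "CR", "D-LOOP": "CR", "A+T RICH REGION": "CR",
}

#: three-letter amino acid -> one-letter, for tRNA-Xxx product strings.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
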