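"""Nucleotide composition, strand skews and codon usage with RSCU.

Strand-asymmetry statistics follow the standard definitions
AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on the
given strand as-is (the caller orients the sequence).  Codon usage is
tabulated under the invertebrate mitochondrial genetic code, and RSCU is
the observed codon count divided by the mean count of its synonymous
family: RSCU(c) = N(c)·|F| / Σ_{c'∈F} N(c').
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import vocab
from .model import CircularAnnotation, extract_region, gene_length


@dataclass
class CompositionProfile:
    """Base counts, percentages and skews for one region class."""

    region: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pct(self, base: str) -> float:
        return self.counts.get(base, 0) / self.total * 100

    @property
    def at_pct(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def at_skew(self) -> float | None:
        a, t = self.counts.get("A", 0), self.counts.get("T", 0)
        return None if a + t == 0 else (a - t) / (a + t)

    @property
    def gc_skew(self) -> float | None:
        g, c = self.counts.get("G", 0), self.counts.get("C", 0)
        return None if g + c == 0 else (g - c) / (g + c)

    def as_row(self) -> dict[str, float | None]:
        """A composition-table row: percentages to 2 dp, skews to 3 dp."""
        r = {b + "%": round(self.pct(b), 2) for b in "ACGT"}
        r["AT%"] = round(self.at_pct, 2)
        r["AT_skew"] = None if self.at_skew is None else round(self.at_skew, 3)
        r["GC_skew"] = None if self.gc_skew is None else round(self.gc_skew, 3)
        return r


def composition(seq: str, region: str = "") -> CompositionProfile:
    """Composition profile of a nucleotide string (ambiguity codes ignored)."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    return CompositionProfile(region,
                              {b: counts.get(b, 0) for b in "ACGT"})


def codon_position_composition(
    cds_regions: list[str] | dict[str, str],
) -> tuple[CompositionProfile, CompositionProfile, CompositionProfile]:
    """Pooled composition at codon positions 1/2/3 across coding regions.

    Regions must be in reading orientation with any incomplete final stop
    nucleotides already excluded; a region whose length is not a multiple
    of three raises, naming the offender.
    """
    items = (cds_regions.items() if isinstance(cds_regions, dict)
             else [(f"region{i}", s) for i, s in enumerate(cds_regions)])
    pools: list[Counter] = [Counter(), Counter(), Counter()]
    for name, seq in items:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{name}: length {len(seq)} not a multiple of 3")
        for k in range(3):
            pools[k].update(seq[k::3])
    return tuple(
        CompositionProfile(f"codon position {k + 1}",
                           {b: pools[k].get(b, 0) for b in "ACGT"})
        for k in range(3)
    )


@dataclass
class CodonUsageTable:
    """Per-codon counts under the invertebrate mitochondrial code.

    Counts include complete stop codons (they enter the percentage
    denominator); incomplete single-T stops contribute nothing.  Codons
    containing ambiguity codes are tallied separately in ``ambiguous``.
    """

    counts: dict[str, int]
    ambiguous: int = 0
    family_mode: str = "amino_acid"     # or "codon_box"

    @classmethod
    def from_counts(cls, counts: dict[str, int], **kw) -> "CodonUsageTable":
        norm = {vocab.normalize_codon(c): int(n) for c, n in counts.items()}
        return cls(counts=norm, **kw)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts.get(vocab.normalize_codon(codon), 0)

    def percentage(self, codon: str) -> float:
        return self.count(codon) / self.total_codons * 100

    def families(self) -> dict[str, tuple[str, ...]]:
        if self.family_mode == "codon_box":
            return vocab.codon_box_families()
        return vocab.amino_acid_families()

    def amino_acid_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for aa, fam in vocab.amino_acid_families().items():
            out[aa] = sum(self.count(c) for c in fam)
        return out

    def rscu(self) -> dict[str, float | None]:
        return rscu(self)


def codon_usage(cds_regions: list[str] | dict[str, str],
                family_mode: str = "amino_acid") -> CodonUsageTable:
    """Tabulate codon usage over in-frame coding regions.

    Regions are read in non-overlapping triplets from position 0; a trailing
    1-2 nt incomplete stop is ignored.
    """
    counts: Counter = Counter()
    ambiguous = 0
    regions = (cds_regions.values() if isinstance(cds_regions, dict)
               else cds_regions)
    for seq in regions:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                ambiguous += 1
    return CodonUsageTable(dict(counts), ambiguous, family_mode)


def rscu(table: CodonUsageTable) -> dict[str, float | None]:
    """Relative synonymous codon usage for every codon in the table's code.

    Families with zero total leave their members' RSCU undefined (None).
    Σ RSCU over each family equals the family size exactly (before any
    rounding) whenever the family was observed.
    """
    out: dict[str, float | None] = {}
    for fam in table.families().values():
        fam_total = sum(table.count(c) for c in fam)
        for c in fam:
            out[c] = (None if fam_total == 0
                      else table.count(c) * len(fam) / fam_total)
    return out


# -- whole-genome composition tables -------------------------------------

def pcg_reading_frames(annotation: CircularAnnotation,
                       drop_incomplete_stop: bool = True) -> dict[str, str]:
    """PCG sequences in reading orientation, trimmed to whole codons.

    Single-nucleotide (or two-nucleotide) incomplete stops are removed so
    the result is in-frame for codon statistics.
    """
    out: dict[str, str] = {}
    for rec in annotation.by_class("PCG"):
        region = extract_region(annotation, rec)
        if drop_incomplete_stop:
            region = region[:len(region) - len(region) % 3]
        out[rec.name] = region
    return out


def genome_composition_table(
    annotation: CircularAnnotation,
) -> dict[str, CompositionProfile]:
    """Composition rows: full length, PCGs, codon positions 1-3, tRNAs, rRNAs, CR.

    Multi-gene classes concatenate each member region in its reading
    orientation; full length is the plus strand as stored.
    """
    if annotation.sequence is None:
        raise ValueError("sequence required")
    rows: dict[str, CompositionProfile] = {}
    rows["Full length"] = composition(annotation.sequence, "Full length")
    frames = pcg_reading_frames(annotation, drop_incomplete_stop=False)
    rows["PCGs"] = composition("".join(frames.values()), "PCGs")
    inframe = pcg_reading_frames(annotation)
    p1, p2, p3 = codon_position_composition(inframe)
    rows["1st codon"], rows["2nd codon"], rows["3rd codon"] = p1, p2, p3
    for label, cls in (("tRNA genes", "tRNA"), ("rRNA genes", "rRNA"),
                       ("CR", "control")):
        recs = annotation.by_class(cls)
        if recs:
            cat = "".join(extract_region(annotation, r) for r in recs)
            rows[label] = composition(cat, label)
    return rows


def per_gene_composition(
    annotation: CircularAnnotation,
) -> dict[str, CompositionProfile]:
    """AT%/skew profile per annotated feature, in reading orientation."""
    return {
        rec.name: composition(extract_region(annotation, rec), rec.name)
        for rec in annotation.records
    }
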