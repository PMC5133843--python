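"""Data model for annotated circular mitochondrial genomes.

Coordinates follow the convention of published mitogenome annotation tables:
1-based, inclusive on both ends, on a circle of length ``L``.  A feature may
wrap the origin, in which case ``end < start`` and its span runs
``start..L`` followed by ``1..end``.  All internal arithmetic converts to
0-based half-open intervals at the boundary and back.

``strand`` is ``"+"`` for the strand of *cox1* and ``"-"`` for the other
strand; a record's *reading orientation* is 5'->3' on its own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import vocab


class ValidationError(ValueError):
    """Annotation violates a structural invariant."""


class ParseError(ValueError):
    """Malformed input file."""


# Length bounds by feature class (bp).
TRNA_LENGTH_RANGE = (50, 100)
PCG_MIN_LENGTH = 90


@dataclass
class GeneRecord:
    """One annotated feature: a row of a mitogenome annotation table."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start only when wrapping the origin
    strand: str = "+"
    gene_class: str = ""
    start_codon: str | None = None
    stop_codon: str | None = None   # triplet or the incomplete-stop token "T-"
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_class:
            self.gene_class = vocab.CLASS_OF.get(self.name, "noncoding")

    def length(self, genome_length: int) -> int:
        return gene_length(self, genome_length)

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def has_incomplete_stop(self) -> bool:
        return self.stop_codon == "T-"


def gene_length(record: GeneRecord, genome_length: int) -> int:
    """Feature length in bp with circular wrap-around.

    Non-wrapping: ``end - start + 1``; wrapping the origin:
    ``L - start + 1 + end``.
    """
    if record.end >= record.start:
        return record.end - record.start + 1
    return genome_length - record.start + 1 + record.end


def _validate_record(rec: GeneRecord, L: int, permissive: bool) -> None:
    if not (1 <= rec.start <= L) or not (1 <= rec.end <= L):
        raise ValidationError(
            f"{rec.name}: coordinates {rec.start}-{rec.end} outside [1, {L}]"
        )
    if rec.strand not in ("+", "-"):
        raise ValidationError(f"{rec.name}: bad strand {rec.strand!r}")
    if rec.gene_class not in vocab.VALID_CLASSES:
        raise ValidationError(f"{rec.name}: bad class {rec.gene_class!r}")
    known = rec.name in vocab.CANONICAL_37 or rec.name in vocab.NONGENE_NAMES
    if not known and not permissive:
        raise ValidationError(f"unknown gene name {rec.name!r}")
    n = gene_length(rec, L)
    if n < 1:
        raise ValidationError(f"{rec.name}: non-positive length")
    if not permissive:
        if rec.gene_class == "tRNA" and not (
            TRNA_LENGTH_RANGE[0] <= n <= TRNA_LENGTH_RANGE[1]
        ):
            raise ValidationError(f"{rec.name}: tRNA length {n} outside "
                                  f"{TRNA_LENGTH_RANGE}")
        if rec.gene_class == "PCG" and n < PCG_MIN_LENGTH:
            raise ValidationError(f"{rec.name}: PCG length {n} < {PCG_MIN_LENGTH}")
    if rec.anticodon is not None and rec.gene_class != "tRNA":
        raise ValidationError(f"{rec.name}: anticodon on non-tRNA")
    if rec.anticodon is None and rec.gene_class == "tRNA" and not permissive:
        raise ValidationError(f"{rec.name}: tRNA without anticodon")
    if rec.stop_codon == "T-" and rec.gene_class != "PCG":
        raise ValidationError(f"{rec.name}: incomplete stop on non-PCG")


@dataclass
class CircularAnnotation:
    """An annotated circular genome: ordered features plus optional sequence."""

    genome_length: int
    records: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.start, r.end))

    def validate(self, permissive: bool = False,
                 allow_ambiguity: bool = False) -> None:
        if self.genome_length < 1:
            raise ValidationError("genome length must be positive")
        if not self.records:
            raise ValidationError("no records")
        seen: set[str] = set()
        wrapping = 0
        for rec in self.records:
            _validate_record(rec, self.genome_length, permissive)
            if rec.name != "NCR":
                if rec.name in seen:
                    raise ValidationError(f"duplicate gene name {rec.name!r}")
                seen.add(rec.name)
            wrapping += rec.wraps
        if wrapping > 1:
            raise ValidationError("more than one record wraps the origin")
        if self.sequence is not None:
            if len(self.sequence) != self.genome_length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != genome length "
                    f"{self.genome_length}"
                )
            alphabet = set(self.sequence.upper())
            if not allow_ambiguity and not alphabet <= set("ACGT"):
                raise ValidationError(
                    f"ambiguity codes in sequence: {sorted(alphabet - set('ACGT'))}"
                )

    # -- lookups ---------------------------------------------------------

    def get(self, name: str) -> GeneRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(rec.name == name for rec in self.records)

    def by_class(self, gene_class: str) -> list[GeneRecord]:
        return [r for r in self.records if r.gene_class == gene_class]

    def circle_order(self, anchor: str = "cox1") -> list[GeneRecord]:
        """Records in circle order starting at ``anchor`` (if present)."""
        recs = self.records
        if anchor in self:
            i = next(i for i, r in enumerate(recs) if r.name == anchor)
            recs = recs[i:] + recs[:i]
        return list(recs)

    def rotated(self, offset: int) -> "CircularAnnotation":
        """Relabel the origin: old position ``offset + 1`` becomes position 1."""
        L = self.genome_length
        offset %= L

        def shift(p: int) -> int:
            return (p - 1 - offset) % L + 1

        recs = [replace(r, start=shift(r.start), end=shift(r.end))
                for r in self.records]
        seq = None
        if self.sequence is not None:
            seq = self.sequence[offset:] + self.sequence[:offset]
        return CircularAnnotation(L, recs, seq, dict(self.metadata))


def extract_region(annotation: CircularAnnotation, record: GeneRecord) -> str:
    """Feature subsequence in its reading orientation.

    Reverse-strand records are reverse-complemented; origin-wrapping spans
    concatenate the suffix and prefix of the plus-strand sequence.
    """
    if annotation.sequence is None:
        raise ValidationError("sequence required")
    seq = annotation.sequence
    if record.wraps:
        sub = seq[record.start - 1:] + seq[:record.end]
    else:
        sub = seq[record.start - 1:record.end]
    return vocab.revcomp(sub) if record.strand == "-" else sub
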