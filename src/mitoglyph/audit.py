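"""Annotation bookkeeping for circular mitogenomes.

Reproduces the audit a mitogenome report states alongside its annotation
table: the per-junction intergenic/overlap (``inc``) column, the gene
inventory against the canonical 37-gene animal complement, start/stop-codon
rules (ATN starts; TAA/TAG or single-T incomplete stops), tRNA
punctuation-model boundary proposals, and the circular length
reconciliation  Σ lengths − overlaps + gaps = L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import vocab
from .model import CircularAnnotation, GeneRecord, extract_region, gene_length


@dataclass
class Junction:
    upstream: str
    downstream: str
    inc: int   # >0 gap, <0 overlap, 0 abutting


@dataclass
class AdjacencyReport:
    """Circular junction bookkeeping (one junction per record)."""

    junctions: list[Junction]
    total_overlap_bp: int
    n_overlap_junctions: int
    total_intergenic_bp: int          # control-region flanks excluded
    n_intergenic_locations: int
    longest_intergenic: tuple[int, tuple[str, str]] | None
    flags: list[str] = field(default_factory=list)

    def conservation_residual(self, annotation: CircularAnnotation) -> int:
        """Σ lengths + Σ inc − L; zero when the circle closes exactly."""
        total = sum(gene_length(r, annotation.genome_length)
                    for r in annotation.records)
        total += sum(j.inc for j in self.junctions)
        return total - annotation.genome_length


def adjacency_report(annotation: CircularAnnotation) -> AdjacencyReport:
    """Junction list in circle order starting at cox1, with gap/overlap totals.

    The ``inc`` value is attached to the junction *preceding* each record, so
    the first entry is the junction from the last gene on the circle back to
    the anchor.  Gaps at junctions flanking the control region are attributed
    to the CR and excluded from the intergenic totals; the overlap totals
    count every junction with ``inc < 0``.
    """
    L = annotation.genome_length
    order = annotation.circle_order("cox1")
    junctions: list[Junction] = []
    flags: list[str] = []
    for i, rec in enumerate(order):
        prev = order[i - 1]
        inc = (rec.start - prev.end - 1) % L
        if inc > L // 2:
            inc -= L
        junctions.append(Junction(prev.name, rec.name, inc))
        if inc <= -gene_length(rec, L) or inc <= -gene_length(prev, L):
            flags.append(f"containment at {prev.name}->{rec.name} (inc={inc})")
    overlaps = [j for j in junctions if j.inc < 0]
    is_cr = lambda name: annotation.get(name).gene_class == "control"
    gaps = [j for j in junctions
            if j.inc > 0 and not (is_cr(j.upstream) or is_cr(j.downstream))]
    longest = None
    if gaps:
        j = max(gaps, key=lambda j: j.inc)
        longest = (j.inc, (j.upstream, j.downstream))
    return AdjacencyReport(
        junctions=junctions,
        total_overlap_bp=-sum(j.inc for j in overlaps),
        n_overlap_junctions=len(overlaps),
        total_intergenic_bp=sum(j.inc for j in gaps),
        n_intergenic_locations=len(gaps),
        longest_intergenic=longest,
        flags=flags,
    )


@dataclass
class InventoryReport:
    present: frozenset[str]
    absent: frozenset[str]       # of the canonical 37
    extra: tuple[str, ...]       # non-canonical features (CR/NCR excluded)
    n_pcg: int
    n_trna: int
    n_rrna: int


def inventory(annotation: CircularAnnotation) -> InventoryReport:
    """Gene inventory against the canonical 37-gene animal complement."""
    names = [r.name for r in annotation.records]
    present = frozenset(n for n in names if n in vocab.CANONICAL_37)
    extra = tuple(n for n in names
                  if n not in vocab.CANONICAL_37 and n not in vocab.NONGENE_NAMES)
    return InventoryReport(
        present=present,
        absent=frozenset(vocab.CANONICAL_37 - present),
        extra=extra,
        n_pcg=len(annotation.by_class("PCG")),
        n_trna=len(annotation.by_class("tRNA")),
        n_rrna=len(annotation.by_class("rRNA")),
    )


@dataclass
class PcgCodonStatus:
    gene: str
    length: int
    start_codon: str | None
    start_ok: bool               # matches ATN
    stop_codon: str | None
    stop_type: str               # "complete" | "incomplete" | "unknown"
    consistent: bool             # length mod 3 agrees with stop type
    sequence_mismatch: str | None = None


@dataclass
class CodonAudit:
    per_gene: list[PcgCodonStatus]
    pcg_total_bp: int
    pcg_fraction_pct: float
    n_incomplete_stops: int
    complete_codons: int
    amino_acids_excluding_stops: int


def codon_audit(annotation: CircularAnnotation) -> CodonAudit:
    """Start/stop-codon audit and coding totals for the 13 PCGs.

    ``complete_codons`` is (Σ PCG bp − incomplete-stop nucleotides)/3 and
    counts the complete stop codons; ``amino_acids_excluding_stops``
    subtracts them, exposing the two conventions published tables mix.
    """
    L = annotation.genome_length
    per_gene: list[PcgCodonStatus] = []
    total = 0
    trailing = 0      # nucleotides of incomplete stops
    n_complete_stops = 0
    for rec in annotation.by_class("PCG"):
        n = gene_length(rec, L)
        total += n
        start_ok = (rec.start_codon is not None
                    and len(rec.start_codon) == 3
                    and rec.start_codon.startswith("AT"))
        if rec.stop_codon == "T-":
            stop_type = "incomplete"
            rem = n % 3
            consistent = rem in (1, 2)
            trailing += rem if consistent else 1
        elif rec.stop_codon in vocab.STOP_CODONS:
            stop_type = "complete"
            consistent = n % 3 == 0
            n_complete_stops += 1
        else:
            stop_type = "unknown"
            consistent = n % 3 == 0
        mismatch = None
        if annotation.sequence is not None:
            region = extract_region(annotation, rec)
            if rec.start_codon and region[:3] != rec.start_codon:
                mismatch = f"start codon {rec.start_codon} != sequence {region[:3]}"
            elif rec.stop_codon == "T-" and not region.endswith("T"):
                mismatch = f"incomplete stop but region ends {region[-1]}"
            elif stop_type == "complete" and region[-3:] != rec.stop_codon:
                mismatch = f"stop codon {rec.stop_codon} != sequence {region[-3:]}"
        per_gene.append(PcgCodonStatus(rec.name, n, rec.start_codon, start_ok,
                                       rec.stop_codon, stop_type, consistent,
                                       mismatch))
    complete = (total - trailing) // 3
    return CodonAudit(
        per_gene=per_gene,
        pcg_total_bp=total,
        pcg_fraction_pct=round(total / L * 100, 2),
        n_incomplete_stops=sum(1 for g in per_gene if g.stop_type == "incomplete"),
        complete_codons=complete,
        amino_acids_excluding_stops=complete - n_complete_stops,
    )


@dataclass
class BoundaryFinding:
    kind: str                 # "punctuation_trim" | "length_outlier"
    gene: str
    partner: str | None
    old_length: int
    new_length: int | None
    new_boundary: int | None  # proposed reading-end coordinate (1-based)
    stop_type: str | None
    note: str = ""


def _refine_trim(region: str, start_len: int, max_scan: int = 60) -> int:
    """Largest trimmed length <= start_len ending in a valid (in)complete stop.

    ``region`` is the PCG in reading orientation.  A valid end has either
    length % 3 == 0 with a TAA/TAG final codon, or length % 3 == 1 with a
    final T (single-nucleotide incomplete stop).  Falls back to the plain
    trim when nothing is found within ``max_scan`` nt.
    """
    for n in range(start_len, max(start_len - max_scan, 3) - 1, -1):
        if n % 3 == 0 and region[n - 3:n] in vocab.STOP_CODONS:
            return n
        if n % 3 == 1 and region[n - 1] == "T":
            return n
    return start_len


def punctuation_check(
    annotation: CircularAnnotation,
    reference_lengths: dict[str, tuple[int, int]] | None = None,
    max_overlap: int = 3,
    length_tolerance: float = 0.05,
) -> list[BoundaryFinding]:
    """Advisory tRNA-punctuation and length-outlier findings for PCGs.

    Under the punctuation model, mitochondrial transcripts are cleaved at
    tRNA structures, so a PCG annotation running more than ``max_overlap``
    nt into a downstream tRNA is proposed for trimming back to the tRNA
    boundary.  When sequence is available the trimmed end is refined to the
    nearest in-frame complete stop (TAA/TAG) or in-frame single T.
    PCGs whose length falls outside the reference range (or deviates more
    than ``length_tolerance`` from a scalar reference) are flagged as
    re-annotation candidates.
    """
    if reference_lengths is None:
        from .datasets import pcg_reference_lengths
        reference_lengths = pcg_reference_lengths()
    L = annotation.genome_length
    findings: list[BoundaryFinding] = []
    trnas = annotation.by_class("tRNA")
    for pcg in annotation.by_class("PCG"):
        n = gene_length(pcg, L)
        for trna in trnas:
            if pcg.strand == "+" and trna.start <= pcg.end <= trna.end:
                k = pcg.end - trna.start + 1
                new_end_coord = trna.start - 1
            elif pcg.strand == "-" and trna.start <= pcg.start <= trna.end:
                k = trna.end - pcg.start + 1
                new_end_coord = trna.end + 1
            else:
                continue
            if k <= max_overlap or k >= n:
                continue
            new_len = n - k
            if annotation.sequence is not None:
                region = extract_region(annotation, pcg)
                new_len = _refine_trim(region, new_len)
                delta = (n - new_len)
                new_end_coord = (pcg.end - delta if pcg.strand == "+"
                                 else pcg.start + delta)
            stop_type = {0: "complete", 1: "T-", 2: "TA-"}[new_len % 3]
            findings.append(BoundaryFinding(
                "punctuation_trim", pcg.name, trna.name, n, new_len,
                new_end_coord, stop_type,
                note=f"overlaps {trna.name} by {k} bp"))
        ref = reference_lengths.get(pcg.name)
        if ref is not None:
            lo, hi = (ref if isinstance(ref, (tuple, list))
                      else (ref * (1 - length_tolerance),
                            ref * (1 + length_tolerance)))
            if not (lo <= n <= hi):
                findings.append(BoundaryFinding(
                    "length_outlier", pcg.name, None, n, None, None, None,
                    note=f"length {n} outside reference range [{lo}, {hi}]"))
    return findings
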