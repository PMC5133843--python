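"""Ground-truthed synthetic circular mitogenomes.

The generator emulates the structure of a sequenced whitefly-style
mitogenome so that every analysis in this package can be exercised without
downloading an accession: a chosen gene order and strand layout with
planned intergenic gaps and overlaps (the ``inc`` vector), protein-coding
genes built codon-by-codon from a codon-usage profile with ATN starts and
complete or single-T incomplete stops, tRNA genes built from cloverleaf
templates (with or without a DHU arm) that fold by construction, rRNA and
non-coding territory sampled to per-class composition targets, and a
control region carrying a poly-T run plus tandem repeat arrays.

Coding sequence is generated codon-wise (so codon-usage truth is exact by
construction); nucleotide-level composition targets therefore apply to the
non-coding classes and are only approximate for PCGs.  Overlapping
features share sequence: start/stop codons are written first, and tRNA
templates adapt their stems around any nucleotides already fixed, so
overlapped tRNAs still fold perfectly.

Every generated genome carries a truth record listing planted features,
templates, repeats and deletions; the same spec and seed reproduce the
same genome bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import vocab
from .model import CircularAnnotation, GeneRecord, ValidationError
from .rearrange import GeneOrder, apply_events  # noqa: F401  (re-export)
from .trna import DEFAULT_PARAMS, FoldParams, _layouts

#: Default anticodon per tRNA gene (DNA alphabet), matching the published
#: whitefly usage; trnI uses the standard insect GAT.
DEFAULT_ANTICODONS = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "ATT", "trnD": "GTC",
    "trnC": "GCA", "trnE": "TTC", "trnQ": "TTG", "trnG": "TCC",
    "trnH": "GTG", "trnI": "GAT", "trnL1": "TAG", "trnL2": "TAA",
    "trnK": "CTT", "trnM": "CAT", "trnF": "GAA", "trnP": "TGG",
    "trnS1": "TCT", "trnS2": "TGA", "trnT": "TGT", "trnW": "TCA",
    "trnY": "GTA", "trnV": "TAC",
}

#: Composition targets (AT%, AT-skew, GC-skew) per region class.
DEFAULT_COMPOSITION = {
    "tRNA": (77.2, 0.023, 0.145),
    "rRNA": (76.6, 0.092, -0.004),
    "control": (66.9, -0.050, 0.117),
    "noncoding": (70.9, -0.125, 0.149),
}


@dataclass
class PlannedGene:
    """One feature of a genome plan, in circle order."""

    name: str
    size: int
    inc_before: int = 0        # gap (>0) or overlap (<0) to the previous gene
    strand: str = "+"
    gene_class: str = ""
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    has_DHU: bool | None = None     # tRNA only; None = default by identity

    def __post_init__(self) -> None:
        if not self.gene_class:
            self.gene_class = vocab.CLASS_OF.get(self.name, "noncoding")
        if self.gene_class == "tRNA":
            if self.anticodon is None:
                self.anticodon = DEFAULT_ANTICODONS[self.name]
            if self.has_DHU is None:
                self.has_DHU = self.name not in ("trnS1", "trnS2")


@dataclass
class RepeatPlan:
    unit_length: int
    copies: int
    offset: int                # 0-based offset within the CR
    divergence: float = 0.02


@dataclass
class CrPlan:
    polyt_length: int = 12
    polyt_offset: int = 10
    arrays: list[RepeatPlan] = field(default_factory=lambda: [
        RepeatPlan(128, 2, 336), RepeatPlan(19, 8, 650)])


@dataclass
class Deletion:
    gene: str
    mode: str = "unannotated"   # unannotated | remnant | excised


@dataclass
class GenomeSpec:
    """Fully serialisable recipe for one synthetic mitogenome."""

    genes: list[PlannedGene]
    codon_profile: dict[str, float] | None = None
    composition: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    cr_plan: CrPlan = field(default_factory=CrPlan)
    deletions: list[Deletion] = field(default_factory=list)
    fold_params: FoldParams = DEFAULT_PARAMS
    seed: int = 0

    @classmethod
    def camelliae_like(cls, **kw) -> "GenomeSpec":
        """Spec mirroring the bundled A. camelliae annotation, incl. its
        inc vector, codon assignments and anticodons."""
        from .datasets import camelliae_annotation, camelliae_codon_counts
        ann = camelliae_annotation()
        return cls(genes=plan_from_annotation(ann),
                   codon_profile={c: float(n) for c, n in
                                  camelliae_codon_counts().items()},
                   **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def plan_from_annotation(ann: CircularAnnotation) -> list[PlannedGene]:
    """Turn an annotation into a circle-ordered plan (sizes + inc vector)."""
    L = ann.genome_length
    order = ann.circle_order("cox1")
    plan = []
    for i, rec in enumerate(order):
        prev = order[i - 1]
        inc = (rec.start - prev.end - 1) % L
        if inc > L // 2:
            inc -= L
        plan.append(PlannedGene(
            rec.name, rec.length(L), inc, rec.strand, rec.gene_class,
            rec.start_codon, rec.stop_codon, rec.anticodon))
    return plan


@dataclass
class SyntheticGenome:
    annotation: CircularAnnotation
    truth: dict

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=1, default=str)


# -- internals -----------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _probs(target: tuple[float, float, float]) -> np.ndarray:
    at_pct, at_skew, gc_skew = target
    at = at_pct / 100.0
    gc = 1.0 - at
    return np.array([at * (1 + at_skew) / 2, gc * (1 - gc_skew) / 2,
                     gc * (1 + gc_skew) / 2, at * (1 - at_skew) / 2])


def _random_seq(rng: np.random.Generator, n: int,
                target: tuple[float, float, float]) -> str:
    draw = rng.choice(4, size=n, p=_probs(target))
    return _BASES[draw].tobytes().decode()


def solve_trna_layout(n: int, has_dhu: bool,
                      params: FoldParams = DEFAULT_PARAMS):
    """Deterministic arm-placement template for a tRNA of length ``n``.

    Among all grid placements of the requested arm count, the one with the
    most stem pairs wins (ties: lexicographically smallest placement), so
    planted tRNAs clear the fold thresholds by construction.
    """
    best = None
    for lt in _layouts(n, params):
        a, s1, dhu, s2, c, v, t, tl = lt
        if (dhu is not None) != has_dhu:
            continue
        pairs = a + (dhu[0] if dhu else 0) + c + t
        key = (-pairs, a, s1, dhu or (0, 0), s2, c, v, t, tl)
        if best is None or key < best[0]:
            best = (key, lt)
    if best is None:
        raise ValidationError(
            f"no {'4' if has_dhu else '3'}-arm cloverleaf layout of {n} nt")
    return best[1]


class _Genome:
    """Mutable genome array with a fixed-position mask."""

    def __init__(self, L: int):
        self.L = L
        self.seq = [None] * L          # type: list[str | None]
        self.fixed = [False] * L
        self.conflicts: list[str] = []

    def reading_positions(self, start: int, end: int, strand: str) -> list[int]:
        """0-based plus-strand indices in reading order for a span."""
        if end >= start:
            span = list(range(start - 1, end))
        else:
            span = list(range(start - 1, self.L)) + list(range(end))
        return span[::-1] if strand == "-" else span

    def write(self, positions: list[int], text: str, strand: str,
              label: str, force: bool = False, quiet: bool = False) -> None:
        for pos, ch in zip(positions, text):
            value = _COMP[ch] if strand == "-" else ch
            if self.fixed[pos] and not force:
                if self.seq[pos] != value and not quiet:
                    self.conflicts.append(
                        f"{label}: position {pos + 1} wants {value}, "
                        f"fixed as {self.seq[pos]}")
                continue
            self.seq[pos] = value
            self.fixed[pos] = True

    def read_local(self, positions: list[int], strand: str) -> list[str | None]:
        out = []
        for pos in positions:
            ch = self.seq[pos] if self.fixed[pos] else None
            if ch is not None and strand == "-":
                ch = _COMP[ch]
            out.append(ch)
        return out


def _build_trna(rng: np.random.Generator, n: int, layout, anticodon: str,
                forced: list[str | None],
                target: tuple[float, float, float]) -> str:
    """A tRNA sequence for one layout, honouring forced local nucleotides.

    Stems pair Watson-Crick; when one side of a pair is forced the other
    takes its complement, so overlap-constrained tRNAs still fold.
    """
    a, s1, dhu, s2, c, v, tl_t, tl = layout
    local: list[str | None] = list(forced)
    pairs: list[tuple[int, int]] = []
    pairs += [(i, n - 1 - i) for i in range(a)]
    pos = a + s1
    if dhu is not None:
        d, dl = dhu
        pairs += [(pos + i, pos + 2 * d + dl - 1 - i) for i in range(d)]
        pos += 2 * d + dl
    pos += s2
    pairs += [(pos + i, pos + 2 * c + 7 - 1 - i) for i in range(c)]
    loop_start = pos + c
    t0 = pos + 2 * c + 7 + v
    pairs += [(t0 + i, t0 + 2 * tl_t + tl - 1 - i) for i in range(tl_t)]
    for k, ch in enumerate(anticodon):
        idx = loop_start + 2 + k
        if local[idx] is None:
            local[idx] = ch
    # compensate the free-position AT fraction for fixed nucleotides
    # (anticodon, overlap constraints) so the whole gene hits the target;
    # complementary stem pairing itself preserves AT content
    fixed = [ch for ch in local if ch is not None]
    n_free = n - len(fixed)
    at_pct, at_skew, gc_skew = target
    if n_free > 0:
        at_fixed = sum(ch in "AT" for ch in fixed)
        at_free = (at_pct / 100 * n - at_fixed) / n_free
        at_pct = min(max(at_free, 0.05), 0.95) * 100
    probs = _probs((at_pct, at_skew, gc_skew))
    def rand_base() -> str:
        return "ACGT"[rng.choice(4, p=probs)]
    for i, j in pairs:
        if local[i] is not None and local[j] is not None:
            continue
        if local[i] is not None:
            local[j] = _COMP[local[i]]
        elif local[j] is not None:
            local[i] = _COMP[local[j]]
        else:
            b = rand_base()
            local[i], local[j] = b, _COMP[b]
    for idx in range(n):
        if local[idx] is None:
            local[idx] = rand_base()
    return "".join(local)


def _sample_codons(rng: np.random.Generator, k: int,
                   profile: dict[str, float]) -> list[str]:
    codons = sorted(c for c in profile
                    if profile[c] > 0 and vocab.CODON_TO_AA.get(
                        vocab.normalize_codon(c)) not in (None, "*"))
    weights = np.array([profile[c] for c in codons], dtype=float)
    weights /= weights.sum()
    draw = rng.choice(len(codons), size=k, p=weights)
    return [vocab.normalize_codon(codons[i]) for i in draw]


def generate(spec: GenomeSpec, seed: int | None = None,
             with_sequence: bool = True) -> SyntheticGenome:
    """Generate a synthetic mitogenome from a spec.

    Returns the annotated genome (with sequence) and a truth record listing
    every planted feature, tRNA template, repeat array and deletion.
    Identical spec and seed give identical output.  With
    ``with_sequence=False`` only the coordinate layout is produced (fast
    path for annotation-level properties).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = [dataclasses.replace(g) for g in spec.genes]
    deletions = {d.gene: d.mode for d in spec.deletions}
    # excised genes vanish entirely: their territory is handed to the next gap
    kept: list[PlannedGene] = []
    carry = 0
    for g in genes:
        g.inc_before += carry
        carry = 0
        if deletions.get(g.name) == "excised":
            # gene and its territory vanish; its preceding gap merges into
            # the next junction
            carry = g.inc_before
            continue
        kept.append(g)
    if carry and kept:
        kept[0].inc_before += carry
    genes = kept

    # -- coordinates -----------------------------------------------------
    coords: list[tuple[PlannedGene, int, int]] = []
    pos = 1
    for i, g in enumerate(genes):
        if g.size < 1:
            raise ValidationError(f"{g.name}: non-positive size")
        if i == 0:
            start = 1
        else:
            start = pos + g.inc_before
        if start < 1:
            raise ValidationError(
                f"{g.name}: overlap {g.inc_before} exceeds preceding territory")
        if i > 0 and g.inc_before < 0 and (
                -g.inc_before >= coords[-1][0].size
                or -g.inc_before >= g.size):
            raise ValidationError(
                f"{g.name}: overlap {-g.inc_before} exceeds a flanking "
                "gene length")
        end = start + g.size - 1
        coords.append((g, start, end))
        pos = end + 1
    L = coords[-1][2] + genes[0].inc_before
    if L < max(end for _, _, end in coords):
        raise ValidationError("closing gap makes genome shorter than last gene")

    genome = _Genome(L)
    profile = spec.codon_profile or {
        c: 1.0 for c in vocab.ALL_CODONS if vocab.CODON_TO_AA[c] != "*"}
    truth: dict = {"genome_length": L, "seed": int(spec.seed if seed is None
                                                   else seed),
                   "genes": [], "trna_templates": {}, "repeats": [],
                   "deletions": [dataclasses.asdict(d) for d in spec.deletions],
                   "conflicts": []}

    def planted(g: PlannedGene) -> bool:
        # remnant-mode deletions leave random territory, not the gene
        return deletions.get(g.name) != "remnant"

    if not with_sequence:
        records = []
        for g, start, end in coords:
            mode = deletions.get(g.name)
            truth["genes"].append({
                "name": g.name, "start": start, "end": end,
                "strand": g.strand, "class": g.gene_class,
                "annotated": mode is None, "deletion_mode": mode})
            if mode in ("unannotated", "remnant"):
                continue
            records.append(GeneRecord(
                g.name, start, end, g.strand, g.gene_class,
                g.start_codon, g.stop_codon,
                g.anticodon if g.gene_class == "tRNA" else None))
        ann = CircularAnnotation(L, records, None)
        ann.validate()
        return SyntheticGenome(ann, truth)

    # -- pass 1: PCG start/stop codons -----------------------------------
    for g, start, end in coords:
        if g.gene_class != "PCG" or not planted(g):
            continue
        rpos = genome.reading_positions(start, end, g.strand)
        start_codon = g.start_codon or "ATG"
        genome.write(rpos[:3], start_codon, g.strand, g.name)
        if g.stop_codon == "T-":
            rem = g.size % 3
            if rem == 0:
                raise ValidationError(
                    f"{g.name}: incomplete stop but size % 3 == 0")
            genome.write(rpos[-rem:], "TA"[:rem], g.strand, g.name)
        else:
            stop = g.stop_codon or "TAA"
            if g.size % 3:
                raise ValidationError(
                    f"{g.name}: complete stop but size {g.size} % 3 != 0")
            genome.write(rpos[-3:], stop, g.strand, g.name)

    # -- pass 2: tRNAs (adapting to fixed positions) ----------------------
    for g, start, end in coords:
        if g.gene_class != "tRNA" or not planted(g):
            continue
        layout = solve_trna_layout(g.size, bool(g.has_DHU), spec.fold_params)
        rpos = genome.reading_positions(start, end, g.strand)
        forced = genome.read_local(rpos, g.strand)
        seq = _build_trna(rng, g.size, layout, g.anticodon, forced,
                          spec.composition["tRNA"])
        genome.write(rpos, seq, g.strand, g.name, force=False)
        truth["trna_templates"][g.name] = {
            "layout": [layout[0], layout[1], layout[2], layout[3],
                       layout[4], layout[5], layout[6], layout[7]],
            "has_DHU": bool(g.has_DHU), "anticodon": g.anticodon,
            "sequence": seq,
        }

    # -- pass 3: PCG interiors --------------------------------------------
    for g, start, end in coords:
        if g.gene_class != "PCG" or not planted(g):
            continue
        rpos = genome.reading_positions(start, end, g.strand)
        rem = g.size % 3 if g.stop_codon == "T-" else 0
        n_codons = (g.size - rem) // 3 - 1 - (0 if g.stop_codon == "T-" else 1)
        body = "".join(_sample_codons(rng, n_codons, profile))
        # overlap positions already fixed by neighbours win silently
        genome.write(rpos[3:3 + len(body)], body, g.strand, g.name,
                     quiet=True)
        if g.stop_codon != "T-":
            pass  # stop already written in pass 1

    # -- pass 4: control region -------------------------------------------
    for g, start, end in coords:
        if g.gene_class != "control":
            continue
        cr = spec.cr_plan
        target = spec.composition["control"]
        local = list(_random_seq(rng, g.size, target))
        if cr.polyt_length:
            for k in range(cr.polyt_length):
                local[cr.polyt_offset + k] = "T"
            truth["repeats"].append({
                "kind": "polyT", "cr_offset": cr.polyt_offset,
                "length": cr.polyt_length,
                "genome_start": start + cr.polyt_offset})
        for arr in cr.arrays:
            unit = _random_seq(rng, arr.unit_length, target)
            off = arr.offset
            if off + arr.unit_length * arr.copies > g.size:
                raise ValidationError("repeat array exceeds control region")
            for copy in range(arr.copies):
                text = list(unit)
                if arr.divergence > 0 and copy > 0:
                    for j in range(1, len(text) - 1):
                        if rng.random() < arr.divergence:
                            text[j] = "ACGT"[rng.choice(4)]
                for j, ch in enumerate(text):
                    local[off + copy * arr.unit_length + j] = ch
            truth["repeats"].append({
                "kind": "tandem", "unit_length": arr.unit_length,
                "copies": arr.copies, "cr_offset": off,
                "genome_start": start + off,
                "genome_end": start + off + arr.unit_length * arr.copies - 1,
                "unit": unit})
        # control regions have no reading orientation; write on plus strand
        rpos = genome.reading_positions(start, end, "+")
        genome.write(rpos, "".join(local), "+", g.name)

    # -- pass 5: rRNA and remaining territory -----------------------------
    for g, start, end in coords:
        if g.gene_class == "rRNA":
            rpos = genome.reading_positions(start, end, g.strand)
            seq = _random_seq(rng, g.size, spec.composition["rRNA"])
            genome.write(rpos, seq, g.strand, g.name)
    free = [i for i in range(L) if not genome.fixed[i]]
    filler = _random_seq(rng, len(free), spec.composition["noncoding"])
    for i, ch in zip(free, filler):
        genome.seq[i] = ch

    sequence = "".join(genome.seq)  # type: ignore[arg-type]
    records = []
    for g, start, end in coords:
        mode = deletions.get(g.name)
        truth["genes"].append({
            "name": g.name, "start": start, "end": end, "strand": g.strand,
            "class": g.gene_class, "annotated": mode is None,
            "deletion_mode": mode})
        if mode in ("unannotated", "remnant"):
            continue
        records.append(GeneRecord(
            g.name, start, end, g.strand, g.gene_class,
            g.start_codon, g.stop_codon,
            g.anticodon if g.gene_class == "tRNA" else None))
    truth["conflicts"] = genome.conflicts
    ann = CircularAnnotation(L, records, sequence)
    ann.validate()
    return SyntheticGenome(ann, truth)
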