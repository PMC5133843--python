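"""Cloverleaf folding, identity assignment and rescue of mitochondrial tRNAs.

A candidate sequence (DNA alphabet, 50-100 nt) is decomposed into the four
cloverleaf arms — acceptor stem, DHU arm (optional: several mitochondrial
tRNAs, classically trnS1, lack it), anticodon arm with a fixed 7-nt loop
carrying the anticodon at loop positions 3-5, and the TψC arm — by
exhaustive search over arm-boundary placements within configured ranges.
G-U wobble pairs count as valid; every other non-Watson-Crick pair is a
mismatch.  The score is pair-count based: valid pairs minus one per
mismatch and minus two for a missing DHU arm; below a valid-pair threshold
no structure is returned.

``rescue_scan`` re-implements the annotation-rescue logic used to recover
tRNA genes that earlier annotations missed: unannotated territory is
scanned on both strands for foldable windows whose anticodon identity
matches a sought gene, optionally corroborated by ungapped similarity to
reference tRNA sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from . import vocab
from .model import CircularAnnotation, GeneRecord
from .vocab import identity_from_anticodon, revcomp

VALID_PAIRS = frozenset(
    ("AT", "TA", "GC", "CG", "GT", "TG")
)


@dataclass(frozen=True)
class FoldParams:
    """Placement ranges and scoring constants for the cloverleaf search."""

    acc_pairs: tuple[int, ...] = (6, 7)
    spacer1: tuple[int, ...] = (1, 2, 3)
    dhu_stem: tuple[int, ...] = (3, 4)        # 0 (absent) handled separately
    dhu_loop: tuple[int, ...] = tuple(range(3, 11))
    spacer2: tuple[int, ...] = (0, 1, 2)
    ac_stem: tuple[int, ...] = (4, 5)
    ac_loop: int = 7
    var_loop: tuple[int, ...] = tuple(range(3, 10))
    t_stem: tuple[int, ...] = (3, 4, 5)
    t_loop: tuple[int, ...] = tuple(range(3, 10))
    min_valid_4arm: int = 18
    min_valid_3arm: int = 14
    mismatch_penalty: int = 1
    missing_arm_penalty: int = 2


DEFAULT_PARAMS = FoldParams()


@dataclass
class TrnaStructure:
    """A cloverleaf decomposition of one sequence."""

    sequence: str
    layout: dict[str, tuple[int, int]]     # segment -> [start, end) local
    pairs: list[tuple[int, int]]
    valid_pairs: int
    mismatch_count: int
    anticodon: str
    has_DHU: bool
    score: int

    @property
    def arms(self) -> tuple[str, ...]:
        base = ("acceptor", "anticodon", "TpsiC")
        return base[:1] + (("DHU",) if self.has_DHU else ()) + base[1:]

    def dot_bracket(self) -> str:
        out = ["." for _ in self.sequence]
        for i, j in self.pairs:
            pair = self.sequence[i] + self.sequence[j]
            if pair in VALID_PAIRS:
                out[i], out[j] = "(", ")"
        return "".join(out)


def _layouts(n: int, p: FoldParams):
    """All arm placements consistent with total length ``n``.

    Yields (a, s1, dhu, s2, c, v, t, tl) with dhu None or (d, dloop); the
    variable-loop length is implied by the remaining nucleotides.
    """
    dhu_options = [None] + [
        (d, dl) for d in p.dhu_stem for dl in p.dhu_loop
    ]
    for a, s1, dhu, s2, c, t, tl in product(
        p.acc_pairs, p.spacer1, dhu_options, p.spacer2,
        p.ac_stem, p.t_stem, p.t_loop,
    ):
        dhu_len = 0 if dhu is None else 2 * dhu[0] + dhu[1]
        v = n - (2 * a + s1 + dhu_len + s2 + 2 * c + p.ac_loop + 2 * t + tl)
        if p.var_loop[0] <= v <= p.var_loop[-1]:
            yield a, s1, dhu, s2, c, v, t, tl


def _build_structure(seq: str, layout_tuple, p: FoldParams) -> TrnaStructure:
    a, s1, dhu, s2, c, v, t, tl = layout_tuple
    n = len(seq)
    pairs: list[tuple[int, int]] = []
    layout: dict[str, tuple[int, int]] = {}
    pos = 0
    layout["acc5"] = (0, a)
    pairs += [(i, n - 1 - i) for i in range(a)]
    pos = a + s1
    if dhu is not None:
        d, dl = dhu
        layout["dhu"] = (pos, pos + 2 * d + dl)
        pairs += [(pos + i, pos + 2 * d + dl - 1 - i) for i in range(d)]
        pos += 2 * d + dl
    pos += s2
    layout["anticodon_arm"] = (pos, pos + 2 * c + p.ac_loop)
    pairs += [(pos + i, pos + 2 * c + p.ac_loop - 1 - i) for i in range(c)]
    loop_start = pos + c
    anticodon = seq[loop_start + 2:loop_start + 5]
    layout["anticodon_loop"] = (loop_start, loop_start + p.ac_loop)
    pos += 2 * c + p.ac_loop
    layout["variable"] = (pos, pos + v)
    pos += v
    layout["tpsic"] = (pos, pos + 2 * t + tl)
    pairs += [(pos + i, pos + 2 * t + tl - 1 - i) for i in range(t)]
    layout["acc3"] = (n - a, n)
    valid = sum(seq[i] + seq[j] in VALID_PAIRS for i, j in pairs)
    mism = len(pairs) - valid
    score = (valid - p.mismatch_penalty * mism
             - (p.missing_arm_penalty if dhu is None else 0))
    return TrnaStructure(seq, layout, pairs, valid, mism, anticodon,
                         dhu is not None, score)


def fold_trna(seq: str, params: FoldParams = DEFAULT_PARAMS,
              allow_ambiguity: bool = False) -> TrnaStructure | None:
    """Best cloverleaf structure of ``seq``, or None below threshold.

    Ties break deterministically: higher score, then more valid pairs,
    fewer mismatches, four arms over three, then the lexicographically
    smallest placement.
    """
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= set("ACGT") and not allow_ambiguity:
        raise ValueError("sequence contains non-ACGT characters")
    best: TrnaStructure | None = None
    best_key = None
    for lt in _layouts(len(seq), params):
        s = _build_structure(seq, lt, params)
        threshold = (params.min_valid_4arm if s.has_DHU
                     else params.min_valid_3arm)
        if s.valid_pairs < threshold:
            continue
        key = (s.score, s.valid_pairs, -s.mismatch_count, s.has_DHU,
               tuple(-x for x in _flat(lt)))
        if best_key is None or key > best_key:
            best, best_key = s, key
    return best


def _flat(lt) -> tuple[int, ...]:
    a, s1, dhu, s2, c, v, t, tl = lt
    d, dl = dhu if dhu is not None else (0, 0)
    return (a, s1, d, dl, s2, c, v, t, tl)


@dataclass
class TrnaIdentity:
    gene: str               # trnX, or "unknown"
    anticodon: str
    codon_family: tuple[str, ...]


def assign_identity(structure: TrnaStructure, strand: str = "+") -> TrnaIdentity:
    """tRNA gene identity from the folded anticodon.

    The anticodon (5'->3') is reverse-complemented to the decoded codon,
    which maps to the amino acid and hence the gene name; Ser and Leu
    resolve to S1/S2 and L1/L2 by codon box.  ``strand`` is recorded by the
    caller and does not alter the mapping (the structure is already in
    reading orientation).
    """
    name = identity_from_anticodon(structure.anticodon)
    if name == "unknown":
        return TrnaIdentity("unknown", structure.anticodon, ())
    codon = revcomp(vocab.normalize_codon(structure.anticodon))
    aa = vocab.CODON_TO_AA[codon]
    fam = tuple(c for c in vocab.amino_acid_families()[aa]
                if vocab.trna_name_for_codon(c) == name)
    return TrnaIdentity(name, structure.anticodon, fam)


def mismatch_census(structures: list[TrnaStructure]) -> int:
    """Total non-Watson-Crick, non-G-U pairs across a set of structures."""
    return sum(s.mismatch_count for s in structures)


# -- rescue of unannotated tRNAs -----------------------------------------

@dataclass
class RescueCandidate:
    record: GeneRecord
    structure: TrnaStructure
    score: int
    similarity: float | None = None


def _scan_windows(s: str, targets: set[str], p: FoldParams,
                  min_len: int, max_len: int,
                  allowed=None) -> list[tuple[int, int, TrnaStructure]]:
    """Anticodon-anchored scan of one oriented sequence.

    Enumerates the same placement grid as :func:`fold_trna`, but anchored at
    candidate anticodon loops whose implied identity is sought, with the
    left (acceptor..anticodon) and right (variable..acceptor) placements
    combined through their additive arm scores.  ``allowed`` optionally
    masks the positions where an anticodon may sit (unannotated territory).
    Returns local windows [ws, we) with their structures, thresholded as in
    ``fold_trna``.
    """
    n = len(s)
    found: list[tuple[int, int, TrnaStructure]] = []
    dhu_options = [None] + [(d, dl) for d in p.dhu_stem for dl in p.dhu_loop]
    for i in range(5, n - 12):
        if allowed is not None and not (allowed[i + 2] and allowed[i + 3]
                                        and allowed[i + 4]):
            continue
        anticodon = s[i + 2:i + 5]
        if identity_from_anticodon(anticodon) not in targets:
            continue
        for c in p.ac_stem:
            if i - c < 0 or i + 7 + c > n:
                continue
            vstem = sum(s[i - c + j] + s[i + 7 + c - 1 - j] in VALID_PAIRS
                        for j in range(c))
            if vstem < c - 1:
                continue
            # left placements: window start per (a, dhu choice)
            left: dict[tuple[int, int], tuple] = {}
            for a, s1, dhu, s2 in product(p.acc_pairs, p.spacer1,
                                          dhu_options, p.spacer2):
                dhu_len = 0 if dhu is None else 2 * dhu[0] + dhu[1]
                ws = i - c - s2 - dhu_len - s1 - a
                if ws < 0:
                    continue
                if dhu is None:
                    dv, contrib = 0, -p.missing_arm_penalty
                else:
                    d, dl = dhu
                    d0 = ws + a + s1
                    dv = sum(s[d0 + j] + s[d0 + 2 * d + dl - 1 - j]
                             in VALID_PAIRS for j in range(d))
                    contrib = dv - p.mismatch_penalty * (d - dv)
                key = (a, ws)
                cand = (contrib, dv, (s1, dhu, s2))
                if key not in left or cand > left[key]:
                    left[key] = cand
            # right placements: end of TψC arm
            right: dict[int, tuple] = {}
            for v, t, tl in product(p.var_loop, p.t_stem, p.t_loop):
                t0 = i + 7 + c + v
                re_end = t0 + 2 * t + tl
                if re_end > n:
                    continue
                tv = sum(s[t0 + j] + s[t0 + 2 * t + tl - 1 - j] in VALID_PAIRS
                         for j in range(t))
                cand = (tv - p.mismatch_penalty * (t - tv), tv, (v, t, tl))
                if re_end not in right or cand > right[re_end]:
                    right[re_end] = cand
            best_here: tuple | None = None
            for (a, ws), (lc, ldv, lcfg) in left.items():
                for re_end, (rc, rtv, rcfg) in right.items():
                    we = re_end + a
                    if we > n or not min_len <= we - ws <= max_len:
                        continue
                    av = sum(s[ws + j] + s[we - 1 - j] in VALID_PAIRS
                             for j in range(a))
                    valid = av + ldv + vstem + rtv
                    has_dhu = lcfg[1] is not None
                    threshold = (p.min_valid_4arm if has_dhu
                                 else p.min_valid_3arm)
                    if valid < threshold:
                        continue
                    s1, dhu, s2 = lcfg
                    v, t, tl = rcfg
                    struct = _build_structure(
                        s[ws:we], (a, s1, dhu, s2, c, v, t, tl), p)
                    cand = (struct.score, struct.valid_pairs, ws, we, struct)
                    if best_here is None or cand[:2] > best_here[:2]:
                        best_here = cand
            if best_here is not None:
                found.append((best_here[2], best_here[3], best_here[4]))
    return found


def _ungapped_similarity(a: str, b: str) -> float:
    """Best ungapped sliding identity of the shorter sequence in the longer."""
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for off in range(len(b) - len(a) + 1):
        ident = sum(x == y for x, y in zip(a, b[off:off + len(a)])) / len(a)
        best = max(best, ident)
    return best


def rescue_scan(
    annotation: CircularAnnotation,
    targets: set[str],
    params: FoldParams = DEFAULT_PARAMS,
    refs: dict[str, str] | None = None,
    min_similarity: float = 0.55,
    boundary_slack: int = 60,
    min_len: int = 50,
    max_len: int = 100,
) -> list[RescueCandidate]:
    """Search unannotated territory for tRNAs in ``targets``.

    Intergenic gaps and non-coding records (each padded by
    ``boundary_slack`` bp into flanking genes) are scanned on both strands;
    windows that fold with a sought anticodon identity and pass the fold
    thresholds become candidates, reduced to the best-scoring candidate per
    locus.  The anticodon itself must lie in unannotated territory, so
    alternative reading frames of annotated genes are never proposed.
    With ``refs`` given (gene name -> reference tRNA sequence), candidates
    additionally need an ungapped similarity of at least
    ``min_similarity`` to their reference.
    """
    if annotation.sequence is None:
        raise ValueError("sequence required")
    if not targets:
        return []
    L = annotation.genome_length
    seq2 = annotation.sequence + annotation.sequence
    # positions covered by annotated features (non-coding spans stay open)
    annotated = [False] * L
    for rec in annotation.records:
        if rec.gene_class == "noncoding":
            continue
        if rec.wraps:
            idxs = list(range(rec.start - 1, L)) + list(range(rec.end))
        else:
            idxs = range(rec.start - 1, rec.end)
        for i in idxs:
            annotated[i] = True
    annotated2 = annotated + annotated
    order = annotation.circle_order("cox1")
    spans: list[tuple[int, int]] = []      # 0-based [start, end) on doubled seq
    for i, rec in enumerate(order):
        prev = order[i - 1]
        inc = (rec.start - prev.end - 1) % L
        if inc > L // 2:
            inc = 0
        if inc > 0:
            spans.append((prev.end % L, prev.end % L + inc))
    for rec in order:
        if rec.gene_class == "noncoding":
            start0 = rec.start - 1
            spans.append((start0, start0 + rec.length(L)))
    candidates: list[RescueCandidate] = []
    for start0, end0 in spans:
        lo = max(0, start0 - boundary_slack)
        hi = min(len(seq2), end0 + boundary_slack)
        fwd = seq2[lo:hi]
        open_fwd = [not a for a in annotated2[lo:hi]]
        for strand, s, mask in (("+", fwd, open_fwd),
                                ("-", revcomp(fwd), open_fwd[::-1])):
            for ws, we, struct in _scan_windows(s, targets, params,
                                                min_len, max_len,
                                                allowed=mask):
                if strand == "+":
                    g0, g1 = lo + ws, lo + we
                else:
                    g0, g1 = hi - we, hi - ws
                ident = assign_identity(struct, strand)
                if ident.gene not in targets:
                    continue
                similarity = None
                if refs is not None and ident.gene in refs:
                    similarity = _ungapped_similarity(struct.sequence,
                                                      refs[ident.gene])
                    if similarity < min_similarity:
                        continue
                start = g0 % L + 1
                end = (g1 - 1) % L + 1
                rec = GeneRecord(ident.gene, start, end, strand, "tRNA",
                                 anticodon=struct.anticodon)
                candidates.append(RescueCandidate(rec, struct, struct.score,
                                                  similarity))
    # best candidate per locus: greedy by score over overlapping spans
    candidates.sort(key=lambda c: (-c.score, -c.structure.valid_pairs,
                                   c.record.start))
    kept: list[RescueCandidate] = []
    for cand in candidates:
        s0 = cand.record.start
        e0 = s0 + cand.structure.sequence.__len__() - 1
        overlapping = False
        for k in kept:
            ks, ke = k.record.start, (k.record.start
                                      + len(k.structure.sequence) - 1)
            if not (e0 < ks or s0 > ke):
                overlapping = True
                break
        if not overlapping:
            kept.append(cand)
    kept.sort(key=lambda c: c.record.start)
    return kept
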