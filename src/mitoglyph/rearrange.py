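"""Gene-order rearrangement analysis on signed circular permutations.

A mitogenome's gene order is modelled as a signed circular permutation
anchored at cox1 with positive sign (sign = strand relative to cox1;
control region and non-coding spans are excluded).  Orders are compared
through oriented adjacencies: the boundary g->h (with signs) counts as
shared with another order if it occurs identically or as its strand-flipped
reversal -h->-g.  The breakpoint distance is the number of adjacencies of
one order (restricted to the common gene set) absent from the other, and
shared + distance = common gene count on circular orders.

Event classification is explicitly heuristic — minimum-event rearrangement
inference is NP-hard in general — and decomposes the observed order into
maximal strips that are consecutive runs of the reference, then labels the
off-anchor strips: flipped in place = inversion, moved without flip =
transposition, moved with flip = inverse transposition; genes absent from
the observed order are losses.  Ties in the anchor choice raise an
ambiguity flag rather than being silently resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SignedGene = tuple[str, int]     # (name, +1 | -1)


@dataclass(frozen=True)
class GeneOrder:
    """Signed circular gene permutation anchored at cox1 forward."""

    genes: tuple[SignedGene, ...]
    label: str = ""

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.label}: duplicate gene names")
        object.__setattr__(self, "genes", self._normalize(self.genes))

    @staticmethod
    def _normalize(genes: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        names = [g for g, _ in genes]
        if "cox1" not in names:
            return tuple(genes)
        i = names.index("cox1")
        rotated = tuple(genes[i:] + genes[:i])
        if rotated[0][1] < 0:    # reflect so the anchor reads forward
            rotated = tuple((g, -s) for g, s in reversed(rotated))
            rotated = GeneOrder._normalize(rotated)
        return rotated

    @classmethod
    def from_strings(cls, tokens: list[str] | str, label: str = "") -> "GeneOrder":
        if isinstance(tokens, str):
            tokens = [t.strip() for t in tokens.split(",")]
        genes = []
        for tok in tokens:
            sign = -1 if tok.startswith("-") else 1
            genes.append((tok.lstrip("+-"), sign))
        return cls(tuple(genes), label)

    @classmethod
    def from_annotation(cls, annotation, label: str = "") -> "GeneOrder":
        """Order of the annotated genes, excluding control/non-coding spans."""
        recs = [r for r in annotation.circle_order("cox1")
                if r.gene_class not in ("control", "noncoding")]
        return cls(tuple((r.name, 1 if r.strand == "+" else -1) for r in recs),
                   label)

    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def restricted(self, keep: set[str]) -> "GeneOrder":
        return GeneOrder(tuple(g for g in self.genes if g[0] in keep),
                         self.label)

    def __len__(self) -> int:
        return len(self.genes)

    def __str__(self) -> str:
        body = ",".join(("" if s > 0 else "-") + g for g, s in self.genes)
        return f"{self.label}: {body}" if self.label else body


def _adjacencies(order: GeneOrder) -> set[tuple[SignedGene, SignedGene]]:
    """Canonicalised oriented adjacencies around the circle."""
    out = set()
    genes = order.genes
    for i in range(len(genes)):
        g, h = genes[i], genes[(i + 1) % len(genes)]
        flipped = ((h[0], -h[1]), (g[0], -g[1]))
        out.add(min((g, h), flipped))
    return out


def shared_boundaries(
    order_a: GeneOrder, order_b: GeneOrder,
) -> tuple[int, list[tuple[SignedGene, SignedGene]]]:
    """Count and list the gene boundaries two orders share.

    Comparison is restricted to the common gene set; a boundary matches if
    present identically or as its strand-flipped reversal.
    """
    common = set(order_a.names()) & set(order_b.names())
    shared = (_adjacencies(order_a.restricted(common))
              & _adjacencies(order_b.restricted(common)))
    return len(shared), sorted(shared)


def breakpoint_distance(order_a: GeneOrder, order_b: GeneOrder) -> int:
    """Adjacencies of one order absent from the other (common genes only)."""
    common = set(order_a.names()) & set(order_b.names())
    if len(common) < 3:
        raise ValueError(f"common gene set too small ({len(common)} < 3)")
    n_shared, _ = shared_boundaries(order_a, order_b)
    return len(common) - n_shared


@dataclass
class RearrangementEvent:
    """One classified difference between a reference and an observed order."""

    type: str                      # inversion | transposition |
    #                                inverse_transposition | gene_loss | remnant
    block: tuple[str, ...]         # gene names, in reference orientation
    destination: str | None = None  # observed upstream gene for moved blocks
    note: str = ""


@dataclass
class EventDecomposition:
    events: list[RearrangementEvent]
    ambiguous: bool = False
    strips: list[tuple[tuple[str, ...], int]] = field(default_factory=list)


def _strips(ref: GeneOrder, obs: GeneOrder):
    """Maximal runs of ``obs`` that are consecutive in ``ref``.

    Yields (members, orientation, ref_start, ref_end) with members in
    observed order; orientation +1 = same ref direction/signs, -1 =
    reversed with flipped signs.
    """
    pos = {g: i for i, (g, _) in enumerate(ref.genes)}
    sgn = {g: s for g, s in ref.genes}
    n = len(ref.genes)
    strips = []
    cur = [obs.genes[0]]
    def rel(g): return g[1] * sgn[g[0]]
    cur_orient = rel(obs.genes[0])
    for g in obs.genes[1:]:
        prev = cur[-1]
        fwd = (pos[g[0]] == (pos[prev[0]] + 1) % n
               and rel(g) == rel(prev) == 1)
        rev = (pos[g[0]] == (pos[prev[0]] - 1) % n
               and rel(g) == rel(prev) == -1)
        if fwd or rev:
            cur.append(g)
            cur_orient = 1 if fwd else -1
        else:
            strips.append((cur, cur_orient if len(cur) > 1 else rel(cur[0])))
            cur = [g]
            cur_orient = rel(g)
    strips.append((cur, cur_orient if len(cur) > 1 else rel(cur[0])))
    out = []
    for members, orient in strips:
        ref_positions = [pos[g] for g, _ in members]
        a = min(ref_positions) if orient == 1 else ref_positions[-1]
        b = max(ref_positions) if orient == 1 else ref_positions[0]
        out.append((members, orient, pos[members[0][0]] if orient == 1 else
                    pos[members[-1][0]], pos[members[-1][0]] if orient == 1
                    else pos[members[0][0]]))
    return out, pos


def classify_events(reference: GeneOrder, observed: GeneOrder) -> EventDecomposition:
    """Greedy strip decomposition of ``observed`` against ``reference``.

    Genes absent from the observed order become ``gene_loss`` events
    (grouped into reference-contiguous blocks); the heaviest chain of
    forward strips in reference order is kept as the anchor, and every
    remaining strip becomes an inversion (flipped in place), transposition
    (moved, unflipped) or inverse transposition (moved and flipped).
    """
    events: list[RearrangementEvent] = []
    obs_names = set(observed.names())
    # losses, grouped by reference contiguity
    lost_block: list[str] = []
    for g, _ in list(reference.genes) + [("", 0)]:
        if g and g not in obs_names:
            lost_block.append(g)
        elif lost_block:
            events.append(RearrangementEvent("gene_loss", tuple(lost_block)))
            lost_block = []
    common = set(reference.names()) & obs_names
    ref_r = reference.restricted(common)
    obs_r = observed.restricted(common)
    strips, pos = _strips(ref_r, obs_r)
    # anchor: max-weight subsequence of forward strips increasing in ref
    # position (the strip containing position 0 / cox1 is the chain root)
    k = len(strips)
    weight = [len(m) for m, *_ in strips]
    starts = [s[2] for s in strips]
    best = [0] * k
    choice_ties = False
    prev_idx: list[int | None] = [None] * k
    for i in range(k):
        if strips[i][1] != 1:
            best[i] = -1
            continue
        best[i] = weight[i]
        for j in range(i):
            if best[j] > 0 and strips[j][1] == 1 and starts[j] < starts[i]:
                cand = best[j] + weight[i]
                if cand > best[i]:
                    best[i], prev_idx[i] = cand, j
                elif cand == best[i] and prev_idx[i] != j:
                    choice_ties = True
    if all(b <= 0 for b in best):
        anchor: set[int] = set()
    else:
        top = max(best)
        ends = [i for i, b in enumerate(best) if b == top]
        if len(ends) > 1:
            choice_ties = True
        i: int | None = ends[0]
        anchor = set()
        while i is not None:
            anchor.add(i)
            i = prev_idx[i]
    obs_list = list(obs_r.genes)
    for idx, (members, orient, a, b) in enumerate(strips):
        if idx in anchor:
            continue
        block_ref_order = tuple(
            g for g, _ in (members if orient == 1 else list(reversed(members)))
        )
        first = members[0]
        i_obs = obs_list.index(first)
        upstream = obs_list[i_obs - 1][0]
        up_pos = pos[upstream]
        in_place = (up_pos == (a - 1) % len(obs_list))
        if orient == -1 and in_place:
            events.append(RearrangementEvent(
                "inversion", block_ref_order, destination=upstream))
        elif orient == -1:
            events.append(RearrangementEvent(
                "inverse_transposition", block_ref_order, destination=upstream))
        else:
            events.append(RearrangementEvent(
                "transposition", block_ref_order, destination=upstream))
    return EventDecomposition(
        events=events, ambiguous=choice_ties,
        strips=[(tuple(g for g, _ in m), o) for m, o, *_ in strips])


def apply_events(order: GeneOrder, events: list[RearrangementEvent],
                 seed: int | None = None) -> GeneOrder:
    """Apply rearrangement events in sequence to an order.

    Blocks are named in their current forward orientation; an event naming
    an absent gene raises.  ``seed`` is accepted for interface symmetry with
    stochastic generators and is unused here.
    """
    genes = list(order.genes)

    def locate(block: tuple[str, ...]) -> tuple[int, bool]:
        names = [g for g, _ in genes]
        for g in block:
            if g not in names:
                raise ValueError(f"event references absent gene {g!r}")
        k = len(block)
        doubled = names + names
        for i in range(len(names)):
            if tuple(doubled[i:i + k]) == block:
                return i, False
            if tuple(reversed(doubled[i:i + k])) == block:
                return i, True
        raise ValueError(f"block {block} not contiguous in current order")

    for ev in events:
        if ev.type == "gene_loss":
            genes = [g for g in genes if g[0] not in ev.block]
            continue
        if ev.type == "remnant":
            continue
        i, reversed_in_order = locate(ev.block)
        k = len(ev.block)
        n = len(genes)
        idxs = [(i + j) % n for j in range(k)]
        block = [genes[j] for j in idxs]
        rest = [genes[j] for j in range(n) if j not in idxs]
        if ev.type == "inversion":
            flipped = [(g, -s) for g, s in reversed(block)]
            out = []
            placed = False
            for j in range(n):
                if j in idxs:
                    if not placed:
                        out.extend(flipped)
                        placed = True
                else:
                    out.append(genes[j])
            genes = out
        elif ev.type in ("transposition", "inverse_transposition"):
            if ev.destination is None:
                raise ValueError(f"{ev.type} requires a destination")
            if ev.type == "inverse_transposition":
                block = [(g, -s) for g, s in reversed(block)]
            dest = next(j for j, (g, _) in enumerate(rest)
                        if g == ev.destination)
            genes = rest[:dest + 1] + block + rest[dest + 1:]
        else:
            raise ValueError(f"unknown event type {ev.type!r}")
    return GeneOrder(tuple(genes), order.label)


def remnant_scan(annotation, reference_order: GeneOrder,
                 min_remnant: int = 40) -> list[RearrangementEvent]:
    """Flag non-coding gaps that sit where the reference predicts a lost gene.

    For each reference gene absent from the annotation whose reference
    flanks are adjacent in the observed order, an intergenic gap of at
    least ``min_remnant`` bp between those flanks is reported as a
    tandem-duplication/random-loss remnant.
    """
    from .audit import adjacency_report

    observed = GeneOrder.from_annotation(annotation)
    obs_names = set(observed.names())
    rep = adjacency_report(annotation)
    gap_at = {}
    for j in rep.junctions:
        gap_at[(j.upstream, j.downstream)] = j.inc
        gap_at[(j.downstream, j.upstream)] = j.inc
    # NCR records themselves count as gaps between their true flanks
    for i, rec in enumerate(annotation.circle_order("cox1")):
        if rec.gene_class == "noncoding":
            order = annotation.circle_order("cox1")
            up = order[i - 1].name
            down = order[(i + 1) % len(order)].name
            span = rec.length(annotation.genome_length)
            gap_at[(up, down)] = gap_at[(down, up)] = span
    events = []
    ref_names = reference_order.names()
    n = len(ref_names)
    obs_adj = {frozenset((a[0], b[0]))
               for a, b in _adjacencies(observed)} | {
        frozenset((observed.genes[i][0],
                   observed.genes[(i + 1) % len(observed)][0]))
        for i in range(len(observed))}
    for i, g in enumerate(ref_names):
        if g in obs_names:
            continue
        up, down = ref_names[i - 1], ref_names[(i + 1) % n]
        if up not in obs_names or down not in obs_names:
            continue
        if frozenset((up, down)) not in obs_adj:
            continue
        gap = gap_at.get((up, down), 0)
        if gap >= min_remnant:
            events.append(RearrangementEvent(
                "remnant", (g,), destination=up,
                note=f"{gap} bp non-coding span between {up} and {down} "
                     f"at the predicted {g} locus"))
    return events


# -- distance matrix and clustering --------------------------------------

def order_distance_matrix(orders: list[GeneOrder]) -> np.ndarray:
    """Pairwise normalised breakpoint distance (distance / common genes)."""
    if len(orders) < 3:
        raise ValueError("need at least 3 orders")
    n = len(orders)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = set(orders[i].names()) & set(orders[j].names())
            d = breakpoint_distance(orders[i], orders[j]) / len(common)
            mat[i, j] = mat[j, i] = d
    return mat


def order_tree(matrix: np.ndarray, labels: list[str]) -> str:
    """Deterministic UPGMA tree over a distance matrix, as newick text.

    Ties in the closest-pair choice break lexicographically on cluster
    labels (each cluster is labelled by its smallest member), so the output
    is reproducible.  A degenerate all-zero matrix yields a star tree with
    a warning.
    """
    if np.allclose(matrix, 0):
        warnings.warn("all distances zero; returning star tree")
        return "(" + ",".join(f"{l}:0" for l in sorted(labels)) + ");"
    clusters: dict[str, tuple[str, float, list[str]]] = {
        lab: (f"{lab}", 0.0, [lab]) for lab in labels
    }
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                dist[frozenset((a, b))] = float(matrix[i, j])
    while len(clusters) > 1:
        pair = min(
            ((dist[frozenset((a, b))], min(a, b), max(a, b))
             for a in clusters for b in clusters if a < b),
        )
        d, a, b = pair
        na, nb = clusters[a], clusters[b]
        height = d / 2
        newick = (f"({na[0]}:{height - na[1]:.6g},"
                  f"{nb[0]}:{height - nb[1]:.6g})")
        members = na[2] + nb[2]
        new_label = min(a, b)
        for c in list(clusters):
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dnew = (dac * len(na[2]) + dbc * len(nb[2])) / len(members)
            dist[frozenset((new_label, c))] = dnew
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[new_label] = (newick, height, members)
    (tree, _, _), = clusters.values()
    return tree + ";"


# -- gene-order file format ----------------------------------------------

def read_gene_orders(path: str | Path) -> dict[str, GeneOrder]:
    """Read 'label: ±gene,±gene,…' lines ('#' comments allowed)."""
    orders: dict[str, GeneOrder] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, body = line.split(":", 1)
        orders[label.strip()] = GeneOrder.from_strings(body, label.strip())
    return orders


def write_gene_orders(orders: dict[str, GeneOrder], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{lab}: {str(o).split(': ')[-1]}\n"
                for lab, o in orders.items()))
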