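"""Tandem-repeat and homopolymer detection for control-region sequence.

Control regions of mitogenomes commonly carry tandem repeat arrays whose
copy number drives genome-size variation, plus poly-T runs.  The scanner
here finds ungapped tandem arrays: for each candidate period it locates
maximal runs where the sequence matches itself shifted by one unit, then
reports maximal non-overlapping regions.  Unit identity is the mean
ungapped identity of consecutive units; there is no indel model, which is
adequate for the short, well-conserved arrays these regions carry.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np


@dataclass
class RepeatRegion:
    """One tandem array: 1-based inclusive span, unit and copy statistics."""

    start: int
    end: int
    unit_length: int
    copy_number: float        # fractional for partial terminal copies
    consensus: str
    identity: float           # mean identity of consecutive unit pairs

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _consensus_and_identity(seq: str, start0: int, end0: int,
                            period: int) -> tuple[str, float]:
    """Majority-vote consensus unit and mean consecutive-unit identity."""
    block = seq[start0:end0]
    n_full = len(block) // period
    units = [block[i * period:(i + 1) * period] for i in range(n_full)]
    cons = "".join(
        Counter(u[j] for u in units).most_common(1)[0][0]
        for j in range(period)
    )
    if n_full < 2:
        return cons, 1.0
    idents = [
        sum(a == b for a, b in zip(units[i], units[i + 1])) / period
        for i in range(n_full - 1)
    ]
    return cons, float(np.mean(idents))


def find_tandem_repeats(seq: str, min_unit: int = 5, max_unit: int = 600,
                        min_copies: float = 2.0,
                        min_identity: float = 0.85) -> list[RepeatRegion]:
    """Detect tandem repeat arrays in ``seq``.

    For each period p, positions where ``seq[i] == seq[i+p]`` are found and
    maximal runs of near-perfect self-match are turned into candidate
    regions of span ``run + p``.  Candidates must reach ``min_copies``
    copies and ``min_identity`` mean unit identity.  Overlapping candidates
    are reduced to maximal non-overlapping regions, preferring the longest
    span and, on ties, the smallest unit; output is sorted by position.
    """
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if max_unit >= n:
        warnings.warn(f"max_unit {max_unit} >= sequence length {n}; clamped")
        max_unit = n - 1
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[RepeatRegion] = []
    kernel_cache: dict[int, np.ndarray] = {}
    for p in range(min_unit, max_unit + 1):
        match = (arr[:-p] == arr[p:]).astype(np.int32)
        if len(match) < p or match.sum() < min_identity * p:
            continue
        # windowed self-match: w[k] = matches in [k, k+p); a position is a
        # valid unit start when a full unit matches the next at >= the
        # identity threshold, which gives crisp array boundaries
        kernel = kernel_cache.setdefault(p, np.ones(p, dtype=np.int32))
        w = np.convolve(match, kernel, mode="valid")
        need = int(np.ceil(min_identity * p))
        good = w >= need
        if not good.any():
            continue
        # maximal runs of good unit starts
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], good.view(np.int8), [0]))))
        for k0, k1 in zip(edges[::2], edges[1::2]):
            # starts k0 .. k1-1 are good; the array spans the first unit,
            # every shifted unit, and the final compared unit
            span = (k1 - 1 - k0) + 2 * p
            if span / p < min_copies:
                continue
            cons, ident = _consensus_and_identity(seq, int(k0),
                                                  int(k0) + span, p)
            if ident >= min_identity:
                candidates.append(RepeatRegion(
                    int(k0) + 1, int(k0) + span, p, round(span / p, 2),
                    cons, ident))
    # parsimony: an array of unit p also self-matches at periods 2p, 3p, ...
    # with a span that can differ by up to one of the larger units, so an
    # overlapping candidate with a larger unit and no real span gain is
    # redundant
    pruned: list[RepeatRegion] = []
    for cand in candidates:
        redundant = any(
            other.unit_length < cand.unit_length
            and not (cand.end < other.start or cand.start > other.end)
            and other.span >= cand.span - cand.unit_length
            for other in candidates
        )
        if not redundant:
            pruned.append(cand)
    # maximal non-overlapping selection: longest span, then smallest unit
    pruned.sort(key=lambda r: (-r.span, r.unit_length, r.start))
    chosen: list[RepeatRegion] = []
    for cand in pruned:
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def find_homopolymers(seq: str, base: str, min_len: int = 8) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` with length >= min_len, as 1-based spans."""
    base = base.upper()
    if base not in "ACGT" or len(base) != 1:
        raise ValueError(f"invalid base {base!r}")
    return [
        (m.start() + 1, m.end())
        for m in re.finditer(f"{base}{{{min_len},}}", seq.upper())
    ]
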