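"""Shared fixtures: the bundled annotation, printed codon counts, and
session-scoped synthetic genomes so expensive generation runs once."""

from __future__ import annotations

import numpy as np
import pytest

import mitoglyph as mg


@pytest.fixture(scope="session")
def camelliae():
    return mg.datasets.camelliae_annotation()


@pytest.fixture(scope="session")
def codon_counts():
    return mg.datasets.camelliae_codon_counts()


@pytest.fixture(scope="session")
def whitefly_orders():
    return mg.datasets.whitefly_gene_orders()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic full-sequence synthetic mitogenome."""
    return mg.generate(mg.GenomeSpec.camelliae_like(seed=7))


def mutate_seq(seq: str, rng: np.random.Generator, rate: float = 0.2) -> str:
    """Point-mutate a sequence (used to emulate a congeneric homolog)."""
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        else:
            out.append(ch)
    return "".join(out)


def random_plan(rng: np.random.Generator) -> list[mg.PlannedGene]:
    """A random but valid circular genome plan (coordinate-level tests)."""
    base = mg.plan_from_annotation(mg.datasets.camelliae_annotation())
    plan = []
    prev_size = base[-1].size
    for g in base:
        size = g.size
        if g.gene_class == "tRNA":
            size = int(rng.integers(52, 90))
        elif g.gene_class in ("rRNA", "control", "noncoding"):
            size = int(rng.integers(200, 1500))
        inc = int(rng.integers(-5, 60))
        if inc < 0:
            inc = -min(-inc, prev_size - 1, size - 1)
        plan.append(mg.PlannedGene(
            g.name, size, inc, g.strand, g.gene_class,
            g.start_codon, g.stop_codon, g.anticodon))
        prev_size = size
    # first gene anchors at position 1; its inc closes the circle
    plan[0].inc_before = abs(plan[0].inc_before)
    return plan
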