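"""Accessors for the small data files bundled with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .model import CircularAnnotation


def _data_path(name: str) -> Path:
    return Path(resources.files("mitoglyph") / "data" / name)


def camelliae_annotation() -> CircularAnnotation:
    """The bundled A. camelliae annotation table (no sequence)."""
    from .io import read_feature_table
    return read_feature_table(_data_path("aleurocanthus_camelliae.tsv"))


def camelliae_codon_counts() -> dict[str, int]:
    """Published per-codon counts for the 13 PCGs (DNA spelling keys)."""
    from .vocab import normalize_codon
    counts: dict[str, int] = {}
    for line in _data_path("camelliae_codon_counts.tsv").read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("codon"):
            continue
        codon, n = line.split("\t")
        counts[normalize_codon(codon)] = int(n)
    return counts


def whitefly_gene_orders() -> "dict[str, object]":
    """Whitefly + ancestral-insect gene orders keyed by label."""
    from .rearrange import read_gene_orders
    return read_gene_orders(_data_path("whitefly_gene_orders.txt"))


def pcg_reference_lengths() -> dict[str, tuple[int, int]]:
    """Family-scale reference PCG length ranges (bp)."""
    raw = yaml.safe_load(_data_path("pcg_reference_lengths.yaml").read_text())
    return {gene: (int(lo), int(hi)) for gene, (lo, hi) in raw.items()}
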