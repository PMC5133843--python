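"""Readers and writers: feature tables (TSV), FASTA and GenBank flat files.

The feature table is the plain-text mirror of a published mitogenome
annotation table: one row per feature with 1-based inclusive coordinates,
preceded by a ``#genome_length=<L>`` header line.  Missing values are ``-``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import SeqIO

from . import vocab
from .model import CircularAnnotation, GeneRecord, ParseError, ValidationError

TABLE_COLUMNS = ("name", "start", "end", "strand", "class",
                 "start_codon", "stop_codon", "anticodon")


def _opt(value: str) -> str | None:
    return None if value in ("-", "", ".") else value


def read_feature_table(path: str | Path, sequence: str | None = None,
                       permissive: bool = False) -> CircularAnnotation:
    """Parse a feature-table TSV into a validated :class:`CircularAnnotation`.

    ``sequence`` may supply the nucleotide string (e.g. read separately from
    FASTA).  With ``permissive=True`` unknown gene names and out-of-range
    feature lengths are tolerated.
    """
    text = Path(path).read_text()
    genome_length: int | None = None
    records: list[GeneRecord] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("genome_length="):
                try:
                    genome_length = int(body.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(
                        f"line {lineno}: bad genome_length header") from exc
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields] != list(TABLE_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected header {TABLE_COLUMNS}")
            header_seen = True
            continue
        if len(fields) != len(TABLE_COLUMNS):
            raise ParseError(
                f"line {lineno}: expected {len(TABLE_COLUMNS)} columns, "
                f"got {len(fields)}")
        name, start, end, strand, cls, startc, stopc, antic = fields
        try:
            rec = GeneRecord(
                name=name.strip(),
                start=int(start),
                end=int(end),
                strand=strand.strip(),
                gene_class=cls.strip(),
                start_codon=_opt(startc.strip()),
                stop_codon=_opt(stopc.strip()),
                anticodon=_opt(antic.strip()),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    if genome_length is None:
        raise ParseError("missing '#genome_length=<L>' header line")
    ann = CircularAnnotation(genome_length, records, sequence)
    ann.validate(permissive=permissive)
    return ann


def write_feature_table(annotation: CircularAnnotation,
                        path: str | Path | None = None) -> str:
    """Serialise an annotation to the canonical TSV; returns the text."""
    out = _io.StringIO()
    out.write(f"#genome_length={annotation.genome_length}\n")
    out.write("\t".join(TABLE_COLUMNS) + "\n")
    for rec in annotation.records:
        out.write("\t".join([
            rec.name, str(rec.start), str(rec.end), rec.strand,
            rec.gene_class,
            rec.start_codon or "-", rec.stop_codon or "-",
            rec.anticodon or "-",
        ]) + "\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# -- FASTA ---------------------------------------------------------------

def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA; returns the upper-cased sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(seq: str, path: str | Path, name: str = "genome",
                width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


# -- GenBank -------------------------------------------------------------

def _map_feature_name(feature) -> str | None:
    """Resolve a GenBank feature to the controlled vocabulary, else None."""
    quals = feature.qualifiers
    candidates = quals.get("gene", []) + quals.get("product", [])
    for raw in candidates:
        key = raw.strip().upper()
        if key in vocab.GENE_SYNONYMS:
            return vocab.GENE_SYNONYMS[key]
        low = raw.strip().lower()
        if low in vocab.CANONICAL_37 or low in ("cr", "ncr"):
            return low if low not in ("cr", "ncr") else low.upper()
        # exact canonical spelling incl. case (nad4L)
        for name in vocab.CANONICAL_37:
            if raw.strip() == name or low == name.lower():
                return name
        if key.startswith("TRNA-") or key.startswith("TRN"):
            aa3 = key.split("-")[-1][:3]
            one = vocab.AA3_TO_1.get(aa3)
            if one in ("S", "L") and one is not None:
                return "trn" + one  # ambiguous; resolved by anticodon below
            if one is not None:
                return "trn" + one
    return None


def _anticodon_from_qualifiers(feature) -> str | None:
    for raw in feature.qualifiers.get("anticodon", []):
        # formats like "(pos:...,aa:Ser,seq:tga)" or a bare triplet
        if "seq:" in raw:
            seq = raw.split("seq:")[1].strip(" )").upper()
        else:
            seq = raw.strip().upper()
        seq = vocab.normalize_codon(seq)
        if len(seq) == 3 and set(seq) <= set("ACGT"):
            return seq
    return None


def read_genbank(path: str | Path, allow_linear: bool = False) -> CircularAnnotation:
    """Read an annotated mitogenome from a GenBank flat file.

    Feature names are mapped onto the controlled vocabulary through the
    synonym map; ``complement()`` spans become reverse-strand records.
    Ambiguous tRNA-Ser/Leu features are resolved by their anticodon
    qualifier.  Features that cannot be mapped are collected in
    ``annotation.metadata["unmapped"]`` rather than silently dropped.
    CDS records whose span is truncated by 1-2 nt relative to a whole number
    of codons, or that carry ``/transl_except``, get the incomplete-stop
    token ``"T-"``.
    """
    record = SeqIO.read(str(path), "genbank")
    topology = record.annotations.get("topology", "")
    if topology != "circular":
        if not allow_linear:
            raise ValidationError(
                "LOCUS does not declare circular topology "
                "(pass allow_linear=True to proceed)")
    L = len(record.seq)
    seq = str(record.seq).upper()
    records: list[GeneRecord] = []
    unmapped: list[str] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        name = _map_feature_name(feat)
        if feat.type == "D-loop":
            name = "CR"
        if name is None:
            unmapped.append(f"{feat.type}@{feat.location}")
            continue
        loc = feat.location
        strand = "-" if loc.strand == -1 else "+"
        start = int(loc.start) + 1          # 0-based -> 1-based
        end = int(loc.end)
        parts = getattr(loc, "parts", [loc])
        if len(parts) > 1:                   # join() wrapping the origin
            first = min(parts, key=lambda p: int(p.start))
            last = max(parts, key=lambda p: int(p.start))
            start, end = int(last.start) + 1, int(first.end)
        cls = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
               "misc_feature": "noncoding", "D-loop": "control"}[feat.type]
        anticodon = _anticodon_from_qualifiers(feat) if cls == "tRNA" else None
        if name in ("trnS", "trnL"):
            if anticodon is not None:
                name = vocab.identity_from_anticodon(anticodon)
            if name in ("trnS", "trnL", "unknown"):
                unmapped.append(f"{feat.type}@{feat.location} "
                                "(Ser/Leu without usable anticodon)")
                continue
        start_codon = stop_codon = None
        if cls == "PCG":
            span = (end - start + 1) if end >= start else (L - start + 1 + end)
            if "transl_except" in feat.qualifiers or span % 3 in (1, 2):
                stop_codon = "T-"
            region = seq[start - 1:end] if end >= start else \
                seq[start - 1:] + seq[:end]
            if strand == "-":
                region = vocab.revcomp(region)
            start_codon = region[:3]
            if stop_codon is None:
                stop_codon = region[-3:]
        if name in seen and name != "NCR":
            unmapped.append(f"duplicate {name}@{feat.location}")
            continue
        seen.add(name)
        records.append(GeneRecord(name, start, end, strand, cls,
                                  start_codon, stop_codon, anticodon))
    if not records:
        raise ValidationError("file has zero mappable features")
    ann = CircularAnnotation(L, records, seq,
                             metadata={"unmapped": unmapped,
                                       "accession": record.id})
    ann.validate(permissive=True)
    return ann
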