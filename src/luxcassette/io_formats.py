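"""Readers and writers for the external formats the pipeline touches.

Formats handled here: protein FASTA (with ``key=value`` header metadata),
GFF3 gene-feature tables, tab-separated domain-hit and tip-metadata tables,
aligned FASTA, and Newick trees (supports as internal node labels).
Validation is strict: malformed input raises ``FormatError`` naming the
offending record or line rather than propagating silently.

Coordinates are 1-based inclusive throughout, the GFF3 convention.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import PhyloTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

GRAM_LABELS = ("positive", "negative", "unknown")
GENE_CLASSES = ("luxI", "luxR", "other")
STRANDS = ("+", "-")

_FASTA_META_KEYS = ("organism", "gram", "phylum", "family", "niche")


class FormatError(ValueError):
    """Raised when an input file violates a format or type invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with organism/gram/taxonomy metadata."""

    id: str
    sequence: str
    organism: str = ""
    gram: str = "unknown"
    phylum: str = ""
    family: str = ""
    niche: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.id!r} contains disallowed letters: {sorted(bad)}"
            )
        if self.gram not in GRAM_LABELS:
            raise FormatError(
                f"protein {self.id!r}: gram must be one of {GRAM_LABELS}, got {self.gram!r}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation on a protein (InterPro- or CDD-style)."""

    protein_id: str
    domain_id: str
    source: str = "interpro"
    start: int | None = None
    end: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("interpro", "cdd"):
            raise FormatError(f"domain hit source must be interpro|cdd, got {self.source!r}")
        if (self.start is None) != (self.end is None):
            raise FormatError(
                f"domain hit {self.domain_id} on {self.protein_id}: start/end must both be set"
            )
        if self.start is not None and not (1 <= self.start <= self.end):
            raise FormatError(
                f"domain hit {self.domain_id} on {self.protein_id}: "
                f"need 1 <= start <= end, got {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval on a replicon: 1-based inclusive, stranded, classified."""

    replicon_id: str
    locus_tag: str
    start: int
    end: int
    strand: str
    gene_class: str = "other"
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"feature {self.locus_tag}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise FormatError(f"feature {self.locus_tag}: coordinates must be positive")
        if self.strand not in STRANDS:
            raise FormatError(f"feature {self.locus_tag}: unknown strand {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise FormatError(
                f"feature {self.locus_tag}: gene_class must be one of {GENE_CLASSES}"
            )

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TipMetadata:
    """Gram label, taxonomy and ecological niche for one tree tip."""

    tip_id: str
    gram: str
    taxonomy: str = ""
    niche: str = ""

    def __post_init__(self) -> None:
        if self.gram not in ("positive", "negative"):
            raise FormatError(
                f"tip {self.tip_id!r}: gram must be positive|negative, got {self.gram!r}"
            )


@dataclass
class Alignment:
    """A multiple sequence alignment: parallel lists of ids and equal-length rows."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise FormatError("alignment: ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("alignment contains duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise FormatError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def matrix(self) -> np.ndarray:
        """Rows as a (n_seqs, n_cols) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="<U1")

    def take_columns(self, index: Sequence[int]) -> "Alignment":
        """New alignment from 0-based column indices (with repetition allowed)."""
        mat = self.matrix()[:, list(index)]
        return Alignment(list(self.ids), ["".join(r) for r in mat])


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta_description(description: str) -> tuple[str, dict[str, str]]:
    parts = description.split()
    seq_id = parts[0]
    meta: dict[str, str] = {}
    for token in parts[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            if key in _FASTA_META_KEYS:
                meta[key] = value
    return seq_id, meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; headers are ``id [key=value]*``.

    Recognised metadata keys: organism, gram, phylum, family, niche; unknown
    keys are ignored.  Duplicate ids raise ``FormatError``; an empty file
    yields an empty list with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, meta = _parse_fasta_description(rec.description)
        if seq_id in seen:
            raise FormatError(f"duplicate FASTA id {seq_id!r} in {path}")
        seen.add(seq_id)
        records.append(ProteinRecord(id=seq_id, sequence=str(rec.seq), **meta))
    if not records:
        warnings.warn(f"FASTA file {path} contains no sequences", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        meta = " ".join(
            f"{key}={getattr(rec, key)}"
            for key in _FASTA_META_KEYS
            if getattr(rec, key) and not (key == "gram" and rec.gram == "unknown")
        )
        description = meta  # SeqIO prints "id description"
        out.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=description))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain-hit TSV (minimal superset of InterProScan TSV; header row mandatory)

_DOMAIN_REQUIRED = ("protein_id", "domain_id", "source")
_DOMAIN_OPTIONAL = ("start", "end", "description")


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read tab-separated domain hits.

    Required columns: protein_id, domain_id, source; optional: start, end,
    description.  Header row is mandatory.
    """
    hits: list[DomainHit] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"domain-hit file {path} is empty", stacklevel=2)
            return []
        missing = set(_DOMAIN_REQUIRED) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"domain-hit file {path} lacks columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            start = row.get("start") or None
            end = row.get("end") or None
            try:
                hits.append(
                    DomainHit(
                        protein_id=row["protein_id"],
                        domain_id=row["domain_id"],
                        source=row["source"],
                        start=int(start) if start is not None else None,
                        end=int(end) if end is not None else None,
                        description=row.get("description") or "",
                    )
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_DOMAIN_REQUIRED + _DOMAIN_OPTIONAL)
        for h in hits:
            writer.writerow(
                [h.protein_id, h.domain_id, h.source,
                 h.start if h.start is not None else "",
                 h.end if h.end is not None else "", h.description]
            )


# ---------------------------------------------------------------------------
# GFF3


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(
    path: str | Path,
    class_map: Mapping[str, str] | None = None,
) -> list[GeneFeature]:
    """Read gene/CDS features from a GFF3 file.

    ``class_map`` maps locus_tag to gene_class (luxI/luxR/other); entries not
    in the map fall back to a ``gene_class`` attribute on the feature line,
    then to ``other``.  Output is sorted by (replicon_id, start).  Coordinate
    or strand violations raise ``FormatError`` with the line number.
    """
    class_map = dict(class_map or {})
    features: list[GeneFeature] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            replicon, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = _parse_gff_attributes(attr_s)
            locus = attrs.get("locus_tag") or attrs.get("ID")
            if not locus:
                raise FormatError(f"{path}:{lineno}: feature lacks locus_tag/ID attribute")
            if (replicon, locus) in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate locus_tag {locus!r} on replicon {replicon!r}"
                )
            seen.add((replicon, locus))
            gene_class = class_map.get(locus, attrs.get("gene_class", "other"))
            try:
                features.append(
                    GeneFeature(
                        replicon_id=replicon,
                        locus_tag=locus,
                        start=start,
                        end=end,
                        strand=strand,
                        gene_class=gene_class,
                        protein_id=attrs.get("protein_id") or None,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not features:
        warnings.warn(f"GFF3 file {path} contains no gene/CDS features", stacklevel=2)
    features.sort(key=lambda f: (f.replicon_id, f.start, f.end, f.locus_tag))
    return features


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}",
                     f"gene_class={f.gene_class}"]
            if f.protein_id:
                attrs.append(f"protein_id={f.protein_id}")
            fh.write(
                "\t".join(
                    [f.replicon_id, "luxcassette", "gene", str(f.start), str(f.end),
                     ".", f.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tip-metadata TSV


def read_tip_metadata(path: str | Path) -> dict[str, TipMetadata]:
    """Read the sidecar tip-metadata table (tip_id, gram, taxonomy, niche)."""
    meta: dict[str, TipMetadata] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "tip_id" not in reader.fieldnames:
            raise FormatError(f"tip-metadata file {path} lacks a tip_id column")
        for lineno, row in enumerate(reader, start=2):
            tip = row["tip_id"]
            if tip in meta:
                raise FormatError(f"{path}:{lineno}: duplicate tip_id {tip!r}")
            try:
                meta[tip] = TipMetadata(
                    tip_id=tip,
                    gram=row.get("gram", ""),
                    taxonomy=row.get("taxonomy", "") or "",
                    niche=row.get("niche", "") or "",
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return meta


def write_tip_metadata(meta: Iterable[TipMetadata], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["tip_id", "gram", "taxonomy", "niche"])
        for m in meta:
            writer.writerow([m.tip_id, m.gram, m.taxonomy, m.niche])


# ---------------------------------------------------------------------------
# Aligned FASTA


def read_alignment(path: str | Path) -> Alignment:
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"alignment file {path} contains no sequences")
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{seq_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> PhyloTree:
    """Read a single Newick tree.

    Numeric internal node labels are interpreted as bootstrap supports in
    [0, 100]; missing branch lengths default to 0.  Unbalanced parentheses
    raise ``FormatError`` with the character offset.
    """
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
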