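"""Pairing of luxI/luxR loci and classification of their gene topology.

A canonical quorum-sensing cassette is a *luxI* synthase gene and a *luxR*
regulator gene on the same replicon within a short genomic distance (3400 bp
by default).  Each pair is rendered as a compact topology string built from
the genomic order, strand orientation and intervening-gene count, e.g.::

    R>I>           adjacent, co-oriented, regulator upstream
    R><I           adjacent, convergent
    <I X(2) R>     two intervening genes, synthase reversed on the left
    R> X(>7) <I    more than seven intervening genes

The intervening-gene count is bucketed as ">7" above seven, matching the
reporting convention of published cassette surveys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GeneFeature

DEFAULT_MAX_GAP_BP = 3400
_INTERVENING_BUCKET = 7


class TopologyError(ValueError):
    pass


def _arrow(gene_class: str, strand: str) -> str:
    letter = "I" if gene_class == "luxI" else "R"
    return f"{letter}>" if strand == "+" else f"<{letter}"


@dataclass(frozen=True)
class TopologyPattern:
    """Relative order/orientation of a luxI-luxR pair, with a canonical render."""

    left_class: str
    left_strand: str
    right_class: str
    right_strand: str
    n_intervening: int

    def __post_init__(self) -> None:
        if {self.left_class, self.right_class} != {"luxI", "luxR"}:
            raise TopologyError("pattern requires one luxI and one luxR gene")
        if self.n_intervening < 0:
            raise TopologyError("n_intervening must be >= 0")

    @property
    def render(self) -> str:
        left = _arrow(self.left_class, self.left_strand)
        right = _arrow(self.right_class, self.right_strand)
        if self.n_intervening == 0:
            return left + right
        count = (
            str(self.n_intervening)
            if self.n_intervening <= _INTERVENING_BUCKET
            else f">{_INTERVENING_BUCKET}"
        )
        return f"{left} X({count}) {right}"


@dataclass(frozen=True)
class CassettePair:
    """A paired luxI/luxR locus with gap, intervening count and topology."""

    luxI: GeneFeature
    luxR: GeneFeature
    gap_bp: int
    n_intervening: int
    pattern: TopologyPattern
    canonical: bool
    overlapping: bool = False

    @property
    def replicon_id(self) -> str:
        return self.luxI.replicon_id


@dataclass(frozen=True)
class PairingResult:
    pairs: tuple[CassettePair, ...]
    solo_luxi: tuple[GeneFeature, ...]
    solo_luxr: tuple[GeneFeature, ...]


def orf_length_aa(feature: GeneFeature) -> int:
    """Protein length encoded by a gene span whose coordinates include the stop.

    (end - start + 1)/3 - 1 residues; spans not divisible by 3 raise
    ``TopologyError`` naming the locus.
    """
    span = feature.span_bp
    if span % 3 != 0:
        raise TopologyError(
            f"locus {feature.locus_tag}: span {span} bp not divisible by 3"
        )
    aa = span // 3 - 1
    if aa == 0:
        warnings.warn(
            f"locus {feature.locus_tag}: zero-residue ORF (lone stop codon)",
            stacklevel=2,
        )
    return aa


def _gap_bp(left: GeneFeature, right: GeneFeature) -> tuple[int, bool]:
    """Bases strictly between two ORFs; overlap yields (0, True)."""
    gap = right.start - left.end - 1
    if gap < 0:
        return 0, True
    return gap, False


def _build_pair(
    luxi: GeneFeature,
    luxr: GeneFeature,
    max_gap_bp: int,
    features_on_replicon: Sequence[GeneFeature],
) -> CassettePair:
    left, right = (luxi, luxr) if luxi.start <= luxr.start else (luxr, luxi)
    gap, overlapping = _gap_bp(left, right)
    if overlapping:
        warnings.warn(
            f"overlapping luxI/luxR pair {luxi.locus_tag}/{luxr.locus_tag}; "
            "gap_bp set to 0",
            stacklevel=3,
        )
    n_intervening = sum(
        1
        for f in features_on_replicon
        if f.gene_class == "other" and f.start > left.end and f.end < right.start
    )
    pattern = TopologyPattern(
        left_class=left.gene_class,
        left_strand=left.strand,
        right_class=right.gene_class,
        right_strand=right.strand,
        n_intervening=n_intervening,
    )
    return CassettePair(
        luxI=luxi,
        luxR=luxr,
        gap_bp=gap,
        n_intervening=n_intervening,
        pattern=pattern,
        canonical=gap <= max_gap_bp,
        overlapping=overlapping,
    )


def pair_cassettes(
    features: Iterable[GeneFeature],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> PairingResult:
    """Pair each luxI with its nearest same-replicon luxR within the gap limit.

    Each luxR is used at most once; a luxI prefers the luxR with the smallest
    gap, then the leftmost.  luxI/luxR genes left unpaired are reported as
    solos.  The result is invariant to input feature order.
    """
    by_replicon: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_replicon.setdefault(f.replicon_id, []).append(f)
    pairs: list[CassettePair] = []
    solo_i: list[GeneFeature] = []
    solo_r: list[GeneFeature] = []
    for replicon in sorted(by_replicon):
        feats = sorted(by_replicon[replicon], key=lambda f: (f.start, f.end, f.locus_tag))
        luxis = [f for f in feats if f.gene_class == "luxI"]
        luxrs = [f for f in feats if f.gene_class == "luxR"]
        available = list(luxrs)
        for luxi in luxis:
            candidates = []
            for luxr in available:
                left, right = (luxi, luxr) if luxi.start <= luxr.start else (luxr, luxi)
                gap, _ = _gap_bp(left, right)
                if gap <= max_gap_bp:
                    candidates.append((gap, luxr.start, luxr))
            if not candidates:
                solo_i.append(luxi)
                continue
            candidates.sort(key=lambda c: (c[0], c[1]))
            chosen = candidates[0][2]
            available.remove(chosen)
            pairs.append(_build_pair(luxi, chosen, max_gap_bp, feats))
        solo_r.extend(available)
    return PairingResult(tuple(pairs), tuple(solo_i), tuple(solo_r))


def classify_topology(
    pair: CassettePair, features_on_replicon: Iterable[GeneFeature]
) -> TopologyPattern:
    """Topology of an existing pair given the full feature set of its replicon.

    Intervening genes are unclassified ("other") features of either strand
    lying wholly inside the gap between the two ORFs.
    """
    feats = sorted(features_on_replicon, key=lambda f: (f.start, f.end))
    rebuilt = _build_pair(pair.luxI, pair.luxR, DEFAULT_MAX_GAP_BP, feats)
    return rebuilt.pattern
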