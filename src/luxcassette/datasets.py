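"""Bundled data: the six published Gram-positive luxI/luxR cassettes.

The coordinate table below is the published survey of canonical luxI/luxR
cassettes found in Gram-positive bacteria (*Asanoa ferruginea*, *Mumia
flava*, *Streptomyces purpurogeneiscleroticus*, *Syntrophaceticus schinkii*),
with RefSeq locus tags, UniProt protein ids, and 1-based inclusive gene
coordinates.  Strands are taken from the arrows of the printed topology
patterns (the table reports coordinates but not strand columns).

The published table also reports intervening-gene buckets ("X(2)", "X(>7)")
without listing the intervening loci themselves; the intervening features
emitted by :func:`published_cassette_features` are therefore SYNTHETIC
placeholder loci planted inside the printed gaps so that topology
classification reproduces the printed bucket.
"""

from __future__ import annotations

from .io_formats import GeneFeature

#: V. fischeri reference proteins used as alignment anchors.
LUXI_REFERENCE_ID = "P12747"
LUXR_REFERENCE_ID = "P12746"

# organism, replicon, (luxI locus, protein, start, end, strand),
# (luxR locus, protein, start, end, strand), n_intervening, expected render
_TABLE = [
    ("Asanoa ferruginea", "Af_rep1",
     ("ADL14_12710", "A0A0M8ZFU8", 3948, 4550, "-"),
     ("ADL14_22475", "A0A0M8ZBK1", 117, 689, "+"), 8, "R> X(>7) <I"),
    ("Asanoa ferruginea", "Af_rep2",
     ("ADL14_01865", "A0A0N0BAZ2", 29123, 29698, "+"),
     ("ADL14_01860", "A0A0N0U2C6", 28172, 28900, "+"), 0, "R>I>"),
    ("Asanoa ferruginea", "Af_rep3",
     ("ADL14_19790", "A0A0N0B7G7", 49967, 50611, "-"),
     ("ADL14_09775", "A0A0M8ZHM1", 49208, 49804, "+"), 0, "R><I"),
    ("Mumia flava", "Mf_rep1",
     ("LK11_10605", "A0A0B2BR17", 94575, 95183, "-"),
     ("LK11_10615", "A0A0B2BQK8", 95914, 96633, "+"), 2, "<I X(2) R>"),
    ("Streptomyces purpurogeneiscleroticus", "Sp_rep1",
     ("ADL19_05265", "A0A0N0B975", 38419, 38994, "+"),
     ("ADL19_05260", "A0A0N0B8Y7", 37479, 38207, "+"), 0, "R>I>"),
    ("Syntrophaceticus schinkii", "Ss_rep1",
     ("SSCH_1110008", "A0A0B7MAK3", 4194, 4883, "-"),
     ("SSCH_1100006", "A0A0B7MIQ5", 3074, 3310, "+"), 8, "R> X(>7) <I"),
]


def _synthetic_intervening_features(
    replicon: str, gap_start: int, gap_end: int, n: int
) -> list[GeneFeature]:
    """Synthetic placeholder loci evenly spaced inside an intergenic gap."""
    gap = gap_end - gap_start + 1
    segment = gap // n
    gene_len = min(300, max(30, segment // 2))
    feats = []
    for i in range(n):
        start = gap_start + i * segment + (segment - gene_len) // 2
        feats.append(
            GeneFeature(
                replicon_id=replicon,
                locus_tag=f"{replicon}_x{i + 1:02d}",
                start=start,
                end=start + gene_len - 1,
                strand="+" if i % 2 == 0 else "-",
                gene_class="other",
            )
        )
    return feats


def published_cassette_features(
    include_intervening: bool = True,
) -> tuple[list[GeneFeature], dict[str, str], list[dict]]:
    """The six published cassettes as GFF3-ready features.

    Returns (features, class_map, expected) where ``expected`` lists, per
    cassette, the replicon, locus tags, gap and the published topology render.
    """
    features: list[GeneFeature] = []
    class_map: dict[str, str] = {}
    expected: list[dict] = []
    for organism, replicon, luxi, luxr, n_x, render in _TABLE:
        gi = GeneFeature(replicon, luxi[0], luxi[2], luxi[3], luxi[4],
                         "luxI", luxi[1])
        gr = GeneFeature(replicon, luxr[0], luxr[2], luxr[3], luxr[4],
                         "luxR", luxr[1])
        features.extend([gi, gr])
        class_map[luxi[0]] = "luxI"
        class_map[luxr[0]] = "luxR"
        left, right = (gi, gr) if gi.start < gr.start else (gr, gi)
        gap = right.start - left.end - 1
        if include_intervening and n_x:
            features.extend(
                _synthetic_intervening_features(
                    replicon, left.end + 1, right.start - 1, n_x
                )
            )
        expected.append(
            {
                "organism": organism,
                "replicon": replicon,
                "luxI_locus": luxi[0],
                "luxR_locus": luxr[0],
                "gap_bp": gap,
                "n_intervening": n_x,
                "pattern": render,
            }
        )
    features.sort(key=lambda f: (f.replicon_id, f.start))
    return features, class_map, expected
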