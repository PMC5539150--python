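"""Synthetic-data generators with planted ground truth for every stage.

Three generators cover the pipeline's inputs:

* :func:`make_replicons` — annotated replicons carrying luxI/luxR cassettes of
  requested topology classes plus decoy solo loci beyond the pairing distance;
* :func:`make_aac_groups` — two protein groups drawn i.i.d. from a background
  amino-acid frequency vector and a multiplicatively shifted copy of it;
* :func:`evolve_on_tree` — a species tree with gram labels monophyletic,
  16S-like and gene alignments evolved under an equal-rates substitution
  process, and horizontal-transfer events planted by regrafting the recipient
  onto a donor branch and re-evolving the gene.

Every generator is a pure function of its scenario's seed and serialises a
truth object sufficient to score the corresponding pipeline stage.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    Alignment,
    GeneFeature,
    ProteinRecord,
    TipMetadata,
)
from .tree import PhyloTree

#: Approximate background amino-acid frequencies of bacterial proteomes
#: (normalised at import time).
BACKGROUND_AA_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}


def _background_vector() -> np.ndarray:
    v = np.array([BACKGROUND_AA_FREQS[aa] for aa in AMINO_ACIDS])
    return v / v.sum()


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class CassetteSpec:
    """One cassette to plant: orientation class, gap and intervening count."""

    left_class: str
    left_strand: str
    right_class: str
    right_strand: str
    gap_bp: int
    n_intervening: int = 0


#: The four topology classes of the published cassette table, with the
#: printed gaps.
TABLE_PATTERN_SPECS = (
    CassetteSpec("luxR", "+", "luxI", "+", 222, 0),    # R>I>
    CassetteSpec("luxR", "+", "luxI", "-", 162, 0),    # R><I
    CassetteSpec("luxI", "-", "luxR", "+", 730, 2),    # <I X(2) R>
    CassetteSpec("luxR", "+", "luxI", "-", 883, 8),    # R> X(>7) <I
)


@dataclass(frozen=True)
class TreeSpec:
    n_gp_tips: int = 6
    n_gn_tips: int = 6
    separation: float = 0.6  # branch length between the two gram clades
    tip_length: tuple[float, float] = (0.05, 0.15)
    internal_length: tuple[float, float] = (0.03, 0.10)


@dataclass(frozen=True)
class HgtEvent:
    tip: str | None = None  # gram-positive recipient; None -> drawn at random
    donor: str | None = None  # gram-negative donor; None -> drawn at random
    genes: str = "both"  # luxI | luxR | both

    def __post_init__(self) -> None:
        if self.genes not in ("luxI", "luxR", "both"):
            raise ScenarioError(f"genes must be luxI|luxR|both, got {self.genes!r}")


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully seeded description of one synthetic study."""

    seed: int = 0
    cassette_specs: tuple[CassetteSpec, ...] = TABLE_PATTERN_SPECS
    n_decoys: int = 2
    decoy_gap_bp: int = 4400  # beyond the default 3400 bp pairing threshold
    aac_shift: Mapping[str, float] = field(default_factory=dict)
    group_sizes: tuple[int, int] = (50, 50)
    aac_length_range: tuple[int, int] = (200, 300)
    tree_spec: TreeSpec = TreeSpec()
    hgt_events: tuple[HgtEvent, ...] = ()
    msa_length: int = 200
    substitution_rate: float = 1.0


# ---------------------------------------------------------------------------
# Replicons


@dataclass(frozen=True)
class RepliconSimulation:
    features: tuple[GeneFeature, ...]
    class_map: dict[str, str]
    truth: dict


def make_replicons(scenario: SyntheticScenario) -> RepliconSimulation:
    """Plant one cassette per replicon plus decoy solos beyond the threshold."""
    rng = np.random.default_rng([scenario.seed, 1])
    features: list[GeneFeature] = []
    class_map: dict[str, str] = {}
    expected_pairs: list[dict] = []
    from .cassette_topology import TopologyPattern  # local to avoid cycle

    for k, spec in enumerate(scenario.cassette_specs):
        if spec.n_intervening and spec.gap_bp < 32 * spec.n_intervening:
            raise ScenarioError(
                f"cassette {k}: {spec.n_intervening} intervening genes do not "
                f"fit in a {spec.gap_bp} bp gap"
            )
        replicon = f"rep{k + 1:02d}"
        left_len = 3 * int(rng.integers(150, 260))
        right_len = 3 * int(rng.integers(150, 260))
        left_start = int(rng.integers(500, 2000))
        left = GeneFeature(
            replicon, f"{replicon}_{spec.left_class}", left_start,
            left_start + left_len - 1, spec.left_strand, spec.left_class,
        )
        right_start = left.end + spec.gap_bp + 1
        right = GeneFeature(
            replicon, f"{replicon}_{spec.right_class}", right_start,
            right_start + right_len - 1, spec.right_strand, spec.right_class,
        )
        features.extend([left, right])
        class_map[left.locus_tag] = spec.left_class
        class_map[right.locus_tag] = spec.right_class
        if spec.n_intervening:
            segment = spec.gap_bp // spec.n_intervening
            gene_len = min(300, max(30, segment // 2))
            for i in range(spec.n_intervening):
                start = left.end + 1 + i * segment + (segment - gene_len) // 2
                features.append(
                    GeneFeature(
                        replicon, f"{replicon}_x{i + 1:02d}", start,
                        start + gene_len - 1,
                        "+" if rng.random() < 0.5 else "-", "other",
                    )
                )
        luxi, luxr = (left, right) if spec.left_class == "luxI" else (right, left)
        pattern = TopologyPattern(
            spec.left_class, spec.left_strand, spec.right_class,
            spec.right_strand, spec.n_intervening,
        )
        expected_pairs.append(
            {
                "replicon": replicon,
                "luxI_locus": luxi.locus_tag,
                "luxR_locus": luxr.locus_tag,
                "gap_bp": spec.gap_bp,
                "n_intervening": spec.n_intervening,
                "pattern": pattern.render,
            }
        )
    solo_tags: list[str] = []
    offset = len(scenario.cassette_specs)
    for k in range(scenario.n_decoys):
        replicon = f"rep{offset + k + 1:02d}"
        start = int(rng.integers(500, 2000))
        luxi = GeneFeature(
            replicon, f"{replicon}_luxI", start, start + 599, "+", "luxI"
        )
        luxr_start = luxi.end + scenario.decoy_gap_bp + 1
        luxr = GeneFeature(
            replicon, f"{replicon}_luxR", luxr_start, luxr_start + 599, "+", "luxR"
        )
        other_start = luxi.end + 200
        other = GeneFeature(
            replicon, f"{replicon}_x01", other_start, other_start + 299, "-", "other"
        )
        features.extend([luxi, luxr, other])
        class_map[luxi.locus_tag] = "luxI"
        class_map[luxr.locus_tag] = "luxR"
        solo_tags.extend([luxi.locus_tag, luxr.locus_tag])
    features.sort(key=lambda f: (f.replicon_id, f.start))
    truth = {"pairs": expected_pairs, "solo_loci": solo_tags}
    return RepliconSimulation(tuple(features), class_map, truth)


# ---------------------------------------------------------------------------
# Amino-acid composition groups


@dataclass(frozen=True)
class AacSimulation:
    group1: tuple[ProteinRecord, ...]  # base frequencies
    group2: tuple[ProteinRecord, ...]  # shifted frequencies
    truth: dict


def make_aac_groups(scenario: SyntheticScenario) -> AacSimulation:
    """Two i.i.d. protein groups; group 2 has multiplicatively shifted residues.

    Sequence lengths are uniform over ``aac_length_range`` (200-300 aa by
    default, the LuxR candidate window).  The truth records the post-
    normalisation expected fold change (group2/group1) per residue.
    """
    rng = np.random.default_rng([scenario.seed, 2])
    base = _background_vector()
    mult = np.array(
        [float(scenario.aac_shift.get(aa, 1.0)) for aa in AMINO_ACIDS]
    )
    if np.any(mult < 0):
        raise ScenarioError("aac_shift multipliers must be non-negative")
    shifted = base * mult
    shifted = shifted / shifted.sum()
    lo, hi = scenario.aac_length_range
    letters = np.array(list(AMINO_ACIDS))

    def draw(n: int, freqs: np.ndarray, prefix: str, gram: str):
        records = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=freqs))
            records.append(
                ProteinRecord(id=f"{prefix}_{i:03d}", sequence=seq, gram=gram)
            )
        return tuple(records)

    n1, n2 = scenario.group_sizes
    group1 = draw(n1, base, "g1", "negative")
    group2 = draw(n2, shifted, "g2", "positive")
    truth = {
        "shifted_residues": sorted(
            aa for aa in scenario.aac_shift if scenario.aac_shift[aa] != 1.0
        ),
        "expected_fc": {
            aa: float(shifted[k] / base[k]) for k, aa in enumerate(AMINO_ACIDS)
        },
    }
    return AacSimulation(group1, group2, truth)


# ---------------------------------------------------------------------------
# Sequence evolution on a tree with planted transfers


class _SimNode:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None, length: float,
                 children: list["_SimNode"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["_SimNode"]:
        if self.is_leaf():
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def newick(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def _random_clade(names: list[str], rng: np.random.Generator,
                  spec: TreeSpec) -> _SimNode:
    nodes = [_SimNode(n, float(rng.uniform(*spec.tip_length))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = _SimNode(None, float(rng.uniform(*spec.internal_length)), [a, b])
        nodes.append(parent)
    return nodes[0]


def _leaf_depths(node: _SimNode, acc: float = 0.0) -> dict[str, float]:
    if node.is_leaf():
        return {node.name: acc + node.length}
    out: dict[str, float] = {}
    for c in node.children:
        out.update(_leaf_depths(c, acc + node.length))
    return out


def _regraft(root: _SimNode, recipient: str, donor: str,
             attach_length: float = 0.05) -> _SimNode:
    """Move the recipient leaf next to the donor leaf (midpoint attachment)."""
    root = copy.deepcopy(root)

    def find_parent(node: _SimNode, name: str) -> tuple[_SimNode, _SimNode] | None:
        for c in node.children:
            if c.is_leaf() and c.name == name:
                return node, c
            found = find_parent(c, name)
            if found:
                return found
        return None

    hit = find_parent(root, recipient)
    if hit is None:
        raise ScenarioError(f"recipient tip {recipient!r} not in tree")
    parent, leaf = hit
    parent.children.remove(leaf)
    if len(parent.children) == 1 and parent is not root:
        # suppress the unifurcation by splicing the remaining child upward
        only = parent.children[0]
        only.length += parent.length
        parent.name, parent.length = only.name, only.length
        parent.children = only.children
    hit = find_parent(root, donor)
    if hit is None:
        raise ScenarioError(f"donor tip {donor!r} not in tree")
    _, donor_leaf = hit
    half = donor_leaf.length / 2.0
    new_donor = _SimNode(donor_leaf.name, half)
    new_recipient = _SimNode(recipient, attach_length)
    donor_leaf.name = None
    donor_leaf.length = half
    donor_leaf.children = [new_donor, new_recipient]
    return root


def _evolve(root: _SimNode, length: int, rate: float,
            rng: np.random.Generator) -> dict[str, str]:
    letters = np.array(list(AMINO_ACIDS))
    n_letters = len(letters)
    root_seq = rng.choice(n_letters, size=length, p=_background_vector())

    out: dict[str, str] = {}

    def mutate(seq: np.ndarray, t: float) -> np.ndarray:
        child = seq.copy()
        p = 1.0 - math.exp(-max(t, 0.0) * rate)
        hits = np.flatnonzero(rng.random(length) < p)
        if hits.size:
            shifts = rng.integers(1, n_letters, size=hits.size)
            child[hits] = (child[hits] + shifts) % n_letters
        return child

    def recurse(node: _SimNode, seq: np.ndarray) -> None:
        child_seq = mutate(seq, node.length)
        if node.is_leaf():
            out[node.name] = "".join(letters[child_seq])
        else:
            for c in node.children:
                recurse(c, child_seq)

    # the root's own edge length does not matter for relative divergence
    for child in root.children:
        recurse(child, root_seq)
    if root.is_leaf():
        out[root.name] = "".join(letters[root_seq])
    return out


@dataclass(frozen=True)
class TreeSimulation:
    species_tree: PhyloTree
    alignments: dict[str, Alignment]  # keys: 16S, luxI, luxR, concat
    metadata: dict[str, TipMetadata]
    truth: dict


_NICHES = ("soil", "plant-associated", "aquatic")


def evolve_on_tree(scenario: SyntheticScenario) -> TreeSimulation:
    """Species tree + evolved alignments with planted transfer events.

    The species tree keeps the gram labels monophyletic (two clades joined
    by a long separating branch).  Each planted event regrafts the recipient
    tip onto the donor's terminal branch in a copy of the tree and re-evolves
    the affected gene alignment there, which guarantees the gene-tree signal
    an incongruence-based detector expects.  The gram-negative leaf closest
    to the inter-clade split is never auto-chosen as donor, so single-gene
    transfers remain distinguishable from both-gene transfers.
    """
    rng = np.random.default_rng([scenario.seed, 3])
    spec = scenario.tree_spec
    gp_names = [f"gp{i + 1:02d}" for i in range(spec.n_gp_tips)]
    gn_names = [f"gn{i + 1:02d}" for i in range(spec.n_gn_tips)]
    gp_clade = _random_clade(gp_names, rng, spec)
    gn_clade = _random_clade(gn_names, rng, spec)
    gp_clade.length = spec.separation / 2.0
    gn_clade.length = spec.separation / 2.0
    species = _SimNode(None, 0.0, [gp_clade, gn_clade])

    # resolve events (donor never the gram-negative leaf nearest the split)
    gn_depths = _leaf_depths(gn_clade, 0.0)
    nearest_gn = min(gn_depths, key=lambda t: (gn_depths[t], t))
    eligible_donors = sorted(set(gn_names) - {nearest_gn})
    used_recipients: set[str] = set()
    events: list[dict] = []
    for ev in scenario.hgt_events:
        tip = ev.tip
        if tip is None:
            free = sorted(set(gp_names) - used_recipients)
            if not free:
                raise ScenarioError("more events than gram-positive tips")
            tip = str(rng.choice(free))
        if tip not in gp_names:
            raise ScenarioError(f"hgt tip {tip!r} not a gram-positive tip")
        donor = ev.donor
        if donor is None:
            donor = str(rng.choice(eligible_donors))
        if donor not in gn_names:
            raise ScenarioError(f"donor {donor!r} not a gram-negative tip")
        used_recipients.add(tip)
        events.append({"tip": tip, "donor": donor, "genes": ev.genes})

    gene_trees = {"luxI": species, "luxR": species}
    for ev in events:
        targets = ("luxI", "luxR") if ev["genes"] == "both" else (ev["genes"],)
        for gene in targets:
            gene_trees[gene] = _regraft(
                gene_trees[gene], ev["tip"], ev["donor"]
            )

    length, rate = scenario.msa_length, scenario.substitution_rate
    seqs_16s = _evolve(species, length, rate, rng)
    seqs_luxi = _evolve(gene_trees["luxI"], length, rate, rng)
    seqs_luxr = _evolve(gene_trees["luxR"], length, rate, rng)
    tips = sorted(seqs_16s)
    alignments = {
        "16S": Alignment(tips, [seqs_16s[t] for t in tips]),
        "luxI": Alignment(tips, [seqs_luxi[t] for t in tips]),
        "luxR": Alignment(tips, [seqs_luxr[t] for t in tips]),
        "concat": Alignment(
            tips, [seqs_luxi[t] + seqs_luxr[t] for t in tips]
        ),
    }
    metadata: dict[str, TipMetadata] = {}
    for t in tips:
        gram = "positive" if t.startswith("gp") else "negative"
        niche = str(rng.choice(_NICHES))
        metadata[t] = TipMetadata(t, gram, taxonomy=gram, niche=niche)
    for ev in events:  # recipient and donor share a niche (ecology corroborates)
        for t in (ev["tip"], ev["donor"]):
            metadata[t] = TipMetadata(
                t, metadata[t].gram, metadata[t].taxonomy, "soil"
            )
    species_newick = f"({gp_clade.newick()},{gn_clade.newick()});"
    return TreeSimulation(
        species_tree=PhyloTree.from_newick(species_newick),
        alignments=alignments,
        metadata=metadata,
        truth={"events": events, "nearest_gn_to_split": nearest_gn},
    )
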