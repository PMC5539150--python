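"""Distance-based tree building, bootstrap, and HGT/co-transfer inference.

Trees are built by neighbor joining (Saitou-Nei Q-criterion) on p- or
Poisson-corrected protein distances, with column-resampling bootstrap
supports.  Horizontal gene transfer between Gram-positive and Gram-negative
bacteria is called from supported gene-tree clades that mix the two gram
groups *and* contradict the reference (16S rRNA) tree's separation of the
groups; ecological-niche agreement is annotated as corroborating evidence
but not required.  Co-transfer of a luxI/luxR cassette is classified by
comparing each cassette's nearest Gram-negative partner across the LuxI,
LuxR and concatenated-protein trees.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_formats import Alignment, TipMetadata
from .tree import PhyloTree, robinson_foulds  # noqa: F401  (re-exported)

GAP_CHARS = frozenset("-.")
DEFAULT_MIN_SUPPORT = 70.0


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered tip list."""

    ids: tuple[str, ...]
    d: np.ndarray
    saturated: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise PhyloError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        finite = self.d[np.isfinite(self.d)]
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if finite.size and finite.min() < 0:
            raise PhyloError("distance matrix has negative entries")


def protein_distance(msa: Alignment, correction: str = "p") -> DistanceMatrix:
    """Pairwise p-distance or Poisson-corrected distance from a protein MSA.

    Only columns where both rows are non-gap are compared; a pair with zero
    comparable columns raises ``PhyloError`` naming the pair.  Poisson
    correction is -ln(1 - p); saturated pairs (p -> 1) are set to inf and
    flagged in ``DistanceMatrix.saturated``.
    """
    if correction not in ("p", "poisson"):
        raise PhyloError(f"unknown correction {correction!r}")
    if msa.n_seqs < 3:
        raise PhyloError("protein_distance needs >= 3 sequences")
    mat = msa.matrix()
    nongap = ~np.isin(mat, list(GAP_CHARS))
    n = msa.n_seqs
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                raise PhyloError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            p = float((mat[i, both] != mat[j, both]).sum()) / compared
            if correction == "poisson":
                if p >= 1.0:
                    d[i, j] = d[j, i] = math.inf
                    saturated.append((msa.ids[i], msa.ids[j]))
                    continue
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(msa.ids), d, tuple(saturated))


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with deterministic lexicographic tie-breaking.

    Negative branch lengths are clamped to zero; the number of clamped
    branches is recorded on the returned tree as ``clamped_negative_branches``.
    The tree is unrooted (trifurcating root node).
    """
    if len(dm.ids) < 3:
        raise PhyloError("neighbor joining needs >= 3 tips")
    if not np.all(np.isfinite(dm.d)):
        raise PhyloError(
            f"distance matrix contains non-finite entries (saturated pairs: "
            f"{dm.saturated})"
        )
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    # cluster key = smallest tip name in the cluster (drives tie-breaks)
    active = sorted(dm.ids)
    index = {name: i for i, name in enumerate(dm.ids)}
    D: dict[str, dict[str, float]] = {
        a: {b: float(dm.d[index[a], index[b]]) for b in active if b != a}
        for a in active
    }
    frag = {a: a for a in active}
    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[a].values()) for a in active}
        best_key: tuple[float, str, str] | None = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                q = (m - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best_key is None or key < best_key:
                    best_key = key
        _, a, b = best_key
        dab = D[a][b]
        la = _clamp(0.5 * dab + (r[a] - r[b]) / (2 * (m - 2)))
        lb = _clamp(dab - (0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))))
        new_frag = f"({frag[a]}:{la:.10g},{frag[b]}:{lb:.10g})"
        new_d = {
            k: max(0.5 * (D[a][k] + D[b][k] - dab), 0.0)
            for k in active
            if k not in (a, b)
        }
        active = [k for k in active if k not in (a, b)]
        for k in active:
            del D[k][a], D[k][b]
        del D[a], D[b], frag[a], frag[b]
        new_key = min(a, b)
        for k in active:
            D[k][new_key] = new_d[k]
        D[new_key] = new_d
        frag[new_key] = new_frag
        active.append(new_key)
        active.sort()
    x, y, z = active
    lx = _clamp(0.5 * (D[x][y] + D[x][z] - D[y][z]))
    ly = _clamp(0.5 * (D[x][y] + D[y][z] - D[x][z]))
    lz = _clamp(0.5 * (D[x][z] + D[y][z] - D[x][y]))
    newick = (
        f"({frag[x]}:{lx:.10g},{frag[y]}:{ly:.10g},{frag[z]}:{lz:.10g});"
    )
    tree = PhyloTree.from_newick(newick)
    tree.clamped_negative_branches = clamped
    return tree


def nj_builder(correction: str = "poisson") -> Callable[[Alignment], PhyloTree]:
    """Alignment -> tree callable: NJ on p/Poisson distances."""

    def build(msa: Alignment) -> PhyloTree:
        return neighbor_joining(protein_distance(msa, correction))

    return build


def bootstrap_support(
    msa: Alignment,
    builder: Callable[[Alignment], PhyloTree] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """Tree on the full alignment with column-bootstrap supports attached.

    Each replicate resamples alignment columns with replacement; the support
    of an internal edge is the percentage of replicate trees containing the
    same bipartition.  Fully reproducible for a given seed.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    builder = builder or nj_builder()
    main = builder(msa)
    rng = np.random.default_rng(seed)
    counts: Counter[frozenset[str]] = Counter()
    for _ in range(n_reps):
        idx = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep = builder(msa.take_columns(idx.tolist()))
        counts.update(rep.bipartitions())
    supports = {
        bp: 100.0 * counts.get(bp, 0) / n_reps for bp in main.bipartitions()
    }
    main.set_supports(supports)
    return main


# ---------------------------------------------------------------------------
# HGT detection


@dataclass(frozen=True)
class HGTCall:
    """A supported gram-mixed gene-tree clade and its verdict."""

    clade_tips: frozenset[str]
    support: float
    mixed: bool
    niche_match: bool
    reference_incongruent: bool
    verdict: str  # hgt_supported | candidate | rejected


def _gram_split(
    tips: Iterable[str], metadata: Mapping[str, TipMetadata]
) -> tuple[set[str], set[str]]:
    pos = {t for t in tips if metadata[t].gram == "positive"}
    neg = {t for t in tips if metadata[t].gram == "negative"}
    return pos, neg


def _reference_label_monophyly(
    reference: PhyloTree, shared: set[str], pos: set[str], neg: set[str]
) -> bool:
    """Does the reference tree separate gram-positive from gram-negative tips?"""
    if len(pos) <= 1 or len(neg) <= 1:
        return True  # a single tip is separated by its own terminal branch
    for side, _sup in reference.internal_clades():
        restricted = side & shared
        if restricted == pos or restricted == neg:
            return True
    return False


def detect_hgt(
    gene_tree: PhyloTree,
    reference_tree: PhyloTree,
    metadata: Mapping[str, TipMetadata],
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> list[HGTCall]:
    """Call HGT from supported gram-mixed clades that contradict the reference.

    For every internal gene-tree edge with support >= ``min_support`` whose
    smaller side (restricted to tips shared with the reference) contains both
    gram labels, a call is emitted.  The call is ``reference_incongruent``
    when the reference tree is label-monophyletic on the shared tips and the
    clade's bipartition is incompatible with that gram-label bipartition
    (i.e. the mixed grouping cannot be drawn on the reference).  Verdict is
    ``hgt_supported`` exactly when mixed, supported and incongruent.
    """
    shared = set(gene_tree.tip_names) & set(reference_tree.tip_names)
    if not shared:
        raise PhyloError("gene and reference trees share no tips")
    missing = sorted(shared - set(metadata))
    if missing:
        raise PhyloError(f"metadata missing for shared tips: {missing}")
    pos, neg = _gram_split(shared, metadata)
    monophyletic = _reference_label_monophyly(reference_tree, shared, pos, neg)
    anchor = min(shared)
    best: dict[frozenset[str], float] = {}
    for side, sup in gene_tree.internal_clades():
        if sup is None or sup < min_support:
            continue
        restricted = side & shared
        complement = shared - restricted
        if len(restricted) < len(complement):
            clade = restricted
        elif len(complement) < len(restricted):
            clade = complement
        else:
            clade = complement if anchor in restricted else restricted
        if len(clade) < 2:
            continue
        if not (clade & pos and clade & neg):
            continue
        key = frozenset(clade)
        if key not in best or sup > best[key]:
            best[key] = sup
    calls: list[HGTCall] = []
    for clade, sup in best.items():
        complement = shared - clade
        incompatible = bool(
            clade & pos and clade & neg and complement & pos and complement & neg
        )
        incongruent = monophyletic and incompatible
        niche_match = any(
            metadata[p].niche
            and metadata[p].niche == metadata[q].niche
            for p in clade & pos
            for q in clade & neg
        )
        calls.append(
            HGTCall(
                clade_tips=clade,
                support=sup,
                mixed=True,
                niche_match=niche_match,
                reference_incongruent=incongruent,
                verdict="hgt_supported" if incongruent else "candidate",
            )
        )
    calls.sort(key=lambda c: (-c.support, sorted(c.clade_tips)))
    return calls


# ---------------------------------------------------------------------------
# Cassette co-transfer classification


@dataclass(frozen=True)
class TransferMode:
    cassette_id: str
    mode: str  # simultaneous | individual | unclear
    partner_luxi: str | None = None
    partner_luxr: str | None = None
    partner_concat: str | None = None
    reason: str = ""


def _nearest_gram_negative(
    tree: PhyloTree,
    tip: str,
    metadata: Mapping[str, TipMetadata],
    dist_cache: dict[int, tuple[list[str], np.ndarray]],
) -> tuple[str | None, float | None]:
    """Nearest gram-negative tip by path length, with placement support.

    Placement support is the bootstrap support of the smallest bipartition
    side containing both the tip and its partner.  Path lengths within 5%
    of the minimum are treated as tied (patristic distances on inferred
    trees carry estimation noise of that order); ties are resolved toward
    the partner sharing the smallest clade with the tip, then the higher
    placement support, then lexicographically.
    """
    key = id(tree)
    if key not in dist_cache:
        dist_cache[key] = tree.tip_distance_matrix()
    ids, d = dist_cache[key]
    if tip not in ids:
        return None, None
    ti = ids.index(tip)
    candidates = [
        (d[ti, ids.index(t)], t)
        for t in ids
        if t != tip and t in metadata and metadata[t].gram == "negative"
    ]
    if not candidates:
        return None, None
    dmin = min(c[0] for c in candidates)
    window = max(1e-12, 0.05 * dmin)
    tied = [t for dist, t in candidates if dist <= dmin + window]
    scored = []
    for t in tied:
        side, sup = tree.smallest_side_containing(tip, t)
        scored.append((len(side), -(sup if sup is not None else -1.0), t, sup))
    scored.sort()
    _, _, partner, support = scored[0]
    return partner, support


def classify_transfer_mode(
    luxi_tree: PhyloTree,
    luxr_tree: PhyloTree,
    concat_tree: PhyloTree,
    cassette_map: Mapping[str, str | tuple[str, str, str]],
    metadata: Mapping[str, TipMetadata],
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> list[TransferMode]:
    """Classify each cassette's transfer as simultaneous/individual/unclear.

    ``cassette_map`` maps cassette id to a single tip name (shared by all
    three trees) or a (luxi_tip, luxr_tip, concat_tip) triple.  A cassette is
    ``simultaneous`` when its nearest Gram-negative partner agrees across the
    LuxI, LuxR and concatenated trees; ``individual`` when the LuxI and LuxR
    partners differ and each placement is supported at >= ``min_support``;
    otherwise ``unclear``.
    """
    trees = {"luxI": luxi_tree, "luxR": luxr_tree, "concat": concat_tree}
    dist_cache: dict[int, tuple[list[str], np.ndarray]] = {}
    out: list[TransferMode] = []
    for cassette_id in sorted(cassette_map):
        spec = cassette_map[cassette_id]
        tips = (
            {"luxI": spec, "luxR": spec, "concat": spec}
            if isinstance(spec, str)
            else dict(zip(("luxI", "luxR", "concat"), spec))
        )
        absent = [
            name for name, tree in trees.items()
            if tips[name] not in set(tree.tip_names)
        ]
        if absent:
            out.append(
                TransferMode(
                    cassette_id, "unclear",
                    reason=f"cassette tip absent from tree(s): {absent}",
                )
            )
            continue
        partners: dict[str, str | None] = {}
        supports: dict[str, float | None] = {}
        for name, tree in trees.items():
            partner, sup = _nearest_gram_negative(
                tree, tips[name], metadata, dist_cache
            )
            partners[name], supports[name] = partner, sup
        if None in partners.values():
            out.append(
                TransferMode(
                    cassette_id, "unclear",
                    partners["luxI"], partners["luxR"], partners["concat"],
                    reason="no gram-negative tips available in some tree",
                )
            )
            continue
        if partners["luxI"] == partners["luxR"] == partners["concat"]:
            mode, reason = "simultaneous", ""
        elif partners["luxI"] != partners["luxR"] and all(
            supports[g] is not None and supports[g] >= min_support
            for g in ("luxI", "luxR")
        ):
            mode, reason = "individual", ""
        else:
            mode, reason = "unclear", "partner disagreement without support"
        out.append(
            TransferMode(
                cassette_id, mode,
                partners["luxI"], partners["luxR"], partners["concat"],
                reason=reason,
            )
        )
    return out
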