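"""Phylogenetic tree container used across the package.

``PhyloTree`` is a thin wrapper over a :class:`dendropy.Tree` that fixes the
conventions the pipeline relies on: numeric internal node labels are bootstrap
supports in [0, 100], missing branch lengths are 0, and bipartitions are
exposed as canonical frozensets of tip names so that trees read from different
sources (or rooted differently) compare cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Raised for malformed Newick input (message includes character offset)."""


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of input (length {len(text)})"
        )


def _label_as_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    if not (0.0 <= value <= 100.0):
        raise NewickParseError(
            f"numeric internal node label {label!r} outside the [0, 100] support range"
        )
    return value


class PhyloTree:
    """Node-labelled tree with branch lengths, supports and named tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
        for node in tree.preorder_node_iter():
            if not hasattr(node, "support"):
                node.support = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        _check_balanced(text)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise NewickParseError(f"Newick parse failure: {exc}") from exc
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.support = None
            else:
                node.support = _label_as_support(node.label)
        obj = cls(tree)
        names = obj.tip_names
        if len(set(names)) != len(names):
            raise NewickParseError("duplicate tip names in tree")
        return obj

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    # -- serialisation ------------------------------------------------------

    def to_newick(self) -> str:
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf():
                sup = getattr(node, "support", None)
                node.label = None if sup is None else f"{sup:g}"
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return text.strip()

    # -- basic accessors ----------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def _node_tipset(self) -> dict[dendropy.Node, frozenset[str]]:
        tipsets: dict[dendropy.Node, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = frozenset([node.taxon.label])
            else:
                tipsets[node] = frozenset().union(
                    *(tipsets[c] for c in node.child_nodes())
                )
        return tipsets

    # -- bipartitions --------------------------------------------------------

    def _canonical(self, side: frozenset[str], all_tips: frozenset[str],
                   anchor: str) -> frozenset[str]:
        return all_tips - side if anchor in side else side

    def bipartition_supports(self) -> dict[frozenset[str], float | None]:
        """Non-trivial bipartitions as canonical tip sets, with edge supports.

        The canonical side of each bipartition is the one NOT containing the
        lexicographically smallest tip, which makes the encoding independent
        of rooting.
        """
        all_tips = frozenset(self.tip_names)
        anchor = min(all_tips)
        tipsets = self._node_tipset()
        out: dict[frozenset[str], float | None] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = tipsets[node]
            if len(side) < 2 or len(side) > len(all_tips) - 2:
                continue
            key = self._canonical(side, all_tips, anchor)
            sup = getattr(node, "support", None)
            if key not in out or (sup is not None and (out[key] is None or sup > out[key])):
                out[key] = sup
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        return set(self.bipartition_supports())

    def internal_clades(self) -> Iterator[tuple[frozenset[str], float | None]]:
        """Yield (child-side tip set, support) for every internal edge."""
        tipsets = self._node_tipset()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            yield tipsets[node], getattr(node, "support", None)

    def set_supports(self, supports: Mapping[frozenset[str], float]) -> None:
        """Attach supports to internal edges keyed by canonical bipartition."""
        all_tips = frozenset(self.tip_names)
        anchor = min(all_tips)
        tipsets = self._node_tipset()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = tipsets[node]
            if len(side) < 2 or len(side) > len(all_tips) - 2:
                continue
            key = self._canonical(side, all_tips, anchor)
            if key in supports:
                node.support = float(supports[key])

    # -- metrics -------------------------------------------------------------

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all tip pairs."""
        leaves = list(self._tree.leaf_node_iter())
        ids = [leaf.taxon.label for leaf in leaves]
        # cumulative distance from each leaf to every ancestor
        up: list[dict[int, float]] = []
        for leaf in leaves:
            acc, node, dist = {}, leaf, 0.0
            while node is not None:
                acc[id(node)] = dist
                dist += node.edge.length or 0.0
                node = node.parent_node
            up.append(acc)
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                common = up[i].keys() & up[j].keys()
                d[i, j] = d[j, i] = min(up[i][k] + up[j][k] for k in common)
        return ids, d

    def smallest_side_containing(
        self, a: str, b: str
    ) -> tuple[frozenset[str], float | None]:
        """Smallest bipartition side holding both tips, with its edge support."""
        all_tips = frozenset(self.tip_names)
        if a not in all_tips or b not in all_tips:
            raise KeyError(f"tips {a!r}/{b!r} not both present in tree")
        tipsets = self._node_tipset()
        best: tuple[int, int, frozenset[str], float | None] | None = None
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = tipsets[node]
            sup = getattr(node, "support", None)
            for candidate in (side, all_tips - side):
                if a in candidate and b in candidate:
                    rank = (len(candidate), 0 if sup is not None else 1)
                    if best is None or rank < (best[0], best[1]):
                        best = (*rank, candidate, sup)
        if best is None:  # only possible side is the full tip set
            return all_tips, None
        return best[2], best[3]


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if set(t1.tip_names) != set(t2.tip_names):
        raise ValueError(
            "Robinson-Foulds distance requires identical tip sets; "
            f"difference: {sorted(set(t1.tip_names) ^ set(t2.tip_names))}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())
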