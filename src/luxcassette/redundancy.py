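"""Greedy identity-threshold clustering to pick representative sequences.

Emulates the CD-HIT style redundancy-reduction step at desk scale: sequences
are sorted by length (longest first) and each joins the first cluster whose
representative it matches at or above the identity threshold, else founds a
new cluster.  Identity comes from a full Needleman-Wunsch global alignment
rather than a k-mer screen — input sizes here make correctness cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_formats import ProteinRecord

#: Traceback preference at equal score: diagonal, then gap in b, then gap in a.
_TB_DIAG, _TB_UP, _TB_LEFT = 0, 1, 2


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]
    threshold: float


def _needleman_wunsch(
    a: str, b: str, match: float, mismatch: float, gap: float
) -> tuple[int, int]:
    """Global alignment; returns (n_matches, alignment_length).

    Linear gap penalty.  Ties are broken diagonal > up > left, so identity is
    deterministic across co-optimal alignments.
    """
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    tb = np.empty((n + 1, m + 1), dtype=np.int8)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    tb[0, :] = _TB_LEFT
    tb[:, 0] = _TB_UP
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_prev = score[i - 1]
        row = score[i]
        tbrow = tb[i]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = row_prev[j] + gap
            left = row[j - 1] + gap
            if diag >= up and diag >= left:
                row[j], tbrow[j] = diag, _TB_DIAG
            elif up >= left:
                row[j], tbrow[j] = up, _TB_UP
            else:
                row[j], tbrow[j] = left, _TB_LEFT
    i, j, matches, length = n, m, 0, 0
    while i > 0 or j > 0:
        move = tb[i, j]
        if i > 0 and j > 0 and move == _TB_DIAG:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and move == _TB_UP:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches, length


def pairwise_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    *,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> float:
    """Global-alignment identity between two sequences.

    Identity = matches / alignment length by default; ``denominator="shorter"``
    divides by the shorter sequence length instead.  Symmetric in its
    arguments.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("pairwise_identity requires non-empty sequences")
    # symmetry under the tie rule: order the inputs canonically
    if (len(sa), sa) > (len(sb), sb):
        sa, sb = sb, sa
    matches, length = _needleman_wunsch(sa, sb, match, mismatch, gap)
    denom = length if denominator == "alignment" else min(len(sa), len(sb))
    return matches / denom


def greedy_cluster(
    proteins: Sequence[ProteinRecord],
    threshold: float = 0.30,
    *,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> list[Cluster]:
    """CD-HIT-style greedy clustering against cluster representatives.

    Sequences are visited longest-first (ties by id); each joins the first
    existing cluster whose representative it matches at >= ``threshold``,
    else founds a new cluster.  Representatives are therefore the longest
    member of each cluster (ties resolved to the lexicographically smallest
    id by the visit order).
    """
    if not proteins:
        raise ValueError("greedy_cluster requires at least one protein")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(proteins, key=lambda p: (-len(p), p.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for p in ordered:
        for k, rep in enumerate(reps):
            if pairwise_identity(p, rep, denominator=denominator) >= threshold:
                members[k].append(p.id)
                break
        else:
            reps.append(p)
            members.append([p.id])
    return [
        Cluster(rep.id, tuple(ids), threshold)
        for rep, ids in zip(reps, members)
    ]


def representatives(clusters: Sequence[Cluster]) -> list[str]:
    return [c.representative_id for c in clusters]
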