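"""Amino-acid composition profiles and two-group fold-change comparison.

Composition of residue x in a protein is Comp(x) = A_x / N, the count of x
over the total residue count (ambiguous "X" residues are excluded from both
numerator and denominator).  Two groups of proteins are compared residue by
residue: fold change is the ratio of group means, the p-value comes from a
two-sided Welch t-test on the per-sequence fractions (Mann-Whitney U as the
rank-based alternative), and a residue is called significant when the fold
change is <= 0.80 or >= 1.20 *and* p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import AMINO_ACIDS, ProteinRecord

FOLD_DOWN = 0.80
FOLD_UP = 1.20
ALPHA = 0.05


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue fractions over the 20 standard amino acids."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.fractions)
        if missing:
            raise ValueError(f"profile lacks residues: {sorted(missing)}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total!r}, not 1")
        if any(not (0.0 <= v <= 1.0) for v in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array([self.fractions[aa] for aa in AMINO_ACIDS])


def composition(record: ProteinRecord | str) -> CompositionProfile:
    """Comp(x) = A_x / N for each standard residue; X excluded throughout."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record.upper()
    counted = [c for c in seq if c != "X"]
    if not counted:
        raise ValueError("sequence has no countable residues")
    n = len(counted)
    return CompositionProfile(
        {aa: counted.count(aa) / n for aa in AMINO_ACIDS}
    )


@dataclass(frozen=True)
class FoldChangeResult:
    residue: str
    group1_mean: float
    group2_mean: float
    fold_change: float
    p_value: float
    significant: bool
    test: str
    degenerate: bool = False  # zero-mean denominator or zero-variance test


def _as_profiles(
    group: Sequence[ProteinRecord | CompositionProfile],
) -> list[CompositionProfile]:
    return [
        g if isinstance(g, CompositionProfile) else composition(g) for g in group
    ]


def _fold_change(m1: float, m2: float) -> tuple[float, bool]:
    if m2 == 0.0:
        if m1 == 0.0:
            return float("nan"), True
        return float("inf"), True
    return m1 / m2, False


def compare_groups(
    group1: Sequence[ProteinRecord | CompositionProfile],
    group2: Sequence[ProteinRecord | CompositionProfile],
    test: Literal["welch", "mannwhitney"] = "welch",
    *,
    fdr: bool = False,
) -> list[FoldChangeResult]:
    """Per-residue fold change and significance between two protein groups.

    Fold change is group1 mean / group2 mean of the per-sequence fractions.
    ``fdr=True`` applies a Benjamini-Hochberg correction to the p-values
    before the significance rule (the default reports raw p-values).
    Both groups need >= 2 members for the Welch test; the rank test is
    suggested otherwise.
    """
    p1 = _as_profiles(group1)
    p2 = _as_profiles(group2)
    if test == "welch" and (len(p1) < 2 or len(p2) < 2):
        raise ValueError(
            "Welch's t-test needs >= 2 sequences per group; "
            "use test='mannwhitney' for smaller groups"
        )
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    x1 = np.array([p.as_vector() for p in p1])  # (n1, 20)
    x2 = np.array([p.as_vector() for p in p2])
    results: list[FoldChangeResult] = []
    pvals: list[float] = []
    for k, aa in enumerate(AMINO_ACIDS):
        a, b = x1[:, k], x2[:, k]
        degenerate = False
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            # both groups constant: identical -> no evidence; else sure difference
            p = 1.0 if a[0] == b[0] else 0.0
            degenerate = True
        elif test == "welch":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        if math.isnan(p):
            p, degenerate = 1.0, True
        pvals.append(p)
        m1, m2 = float(a.mean()), float(b.mean())
        fc, fc_degenerate = _fold_change(m1, m2)
        results.append(
            FoldChangeResult(
                residue=aa,
                group1_mean=m1,
                group2_mean=m2,
                fold_change=fc,
                p_value=p,
                significant=False,  # filled below
                test=test,
                degenerate=degenerate or fc_degenerate,
            )
        )
    adj = _benjamini_hochberg(pvals) if fdr else pvals
    final: list[FoldChangeResult] = []
    for r, p in zip(results, adj):
        sig = (
            not math.isnan(r.fold_change)
            and (r.fold_change <= FOLD_DOWN or r.fold_change >= FOLD_UP)
            and p < ALPHA
        )
        final.append(
            FoldChangeResult(
                r.residue, r.group1_mean, r.group2_mean, r.fold_change,
                p, sig, r.test, r.degenerate,
            )
        )
    return final


def _benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()


def pooled_composition(records: Iterable[ProteinRecord]) -> CompositionProfile:
    """Composition of the concatenated residue pool (length-weighted)."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for rec in records:
        for c in rec.sequence:
            if c != "X":
                counts[c] += 1
                total += 1
    if total == 0:
        raise ValueError("no countable residues in group")
    return CompositionProfile({aa: counts[aa] / total for aa in AMINO_ACIDS})
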