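"""Reference-anchored per-position conservation from a protein MSA.

Each ungapped position of a chosen reference row (e.g. the *V. fischeri* LuxI
sequence) is scored by the percentage of the *other* alignment rows carrying
the reference residue in that column; gaps in non-reference rows count as
mismatches.  A site is "conserved" when that identity percentage reaches the
threshold (50% by default, the smallest value consistent with published
invariant-residue tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import Alignment

DEFAULT_THRESHOLD_PCT = 50.0
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ConservedSite:
    ref_position: int  # 1-based index in the ungapped reference
    ref_residue: str
    alignment_column: int  # 1-based alignment column
    identity_pct: float  # exact value; round for reporting
    conserved: bool


def map_reference_positions(msa: Alignment, ref_id: str) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based ungapped reference positions.

    Gap columns of the reference map to nothing; the mapping is strictly
    monotone.  An all-gap reference row raises ``ValueError``.
    """
    ref_row = msa.row(ref_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[col] = pos
    if not mapping:
        raise ValueError(f"reference {ref_id!r} is all gaps in the alignment")
    return mapping


def site_conservation(
    msa: Alignment,
    ref_id: str,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> list[ConservedSite]:
    """One ConservedSite per ungapped reference position.

    identity_pct is computed over the non-reference rows only.
    """
    if msa.n_seqs < 2:
        raise ValueError("site_conservation needs an alignment of >= 2 sequences")
    ref_row = msa.row(ref_id)
    others = [s for i, s in zip(msa.ids, msa.seqs) if i != ref_id]
    col_to_pos = map_reference_positions(msa, ref_id)
    sites: list[ConservedSite] = []
    for col, pos in col_to_pos.items():
        ref_res = ref_row[col - 1]
        matches = sum(1 for s in others if s[col - 1] == ref_res)
        pct = 100.0 * matches / len(others)
        sites.append(
            ConservedSite(
                ref_position=pos,
                ref_residue=ref_res,
                alignment_column=col,
                identity_pct=pct,
                conserved=pct >= threshold_pct,
            )
        )
    return sites


def conserved_sites(
    msa: Alignment, ref_id: str, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> list[ConservedSite]:
    """Only the sites meeting the conservation threshold."""
    return [s for s in site_conservation(msa, ref_id, threshold_pct) if s.conserved]
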