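"""Domain-based selection of putative LuxI and LuxR candidate proteins.

LuxI synthases are identified by the autoinducer-synthase domain
(InterPro IPR001690).  LuxR regulators must carry *two* domain classes — a
C-terminal helix-turn-helix DNA-binding domain (IPR000792 / IPR011991) *and*
an N-terminal autoinducer/ligand-binding domain (ABD) — so that LuxR-family
two-component response regulators lacking a ligand pocket are excluded.
Length windows bracket the candidate classes (LuxR 200-300 aa; LuxI
150-350 aa, a permissive envelope around the observed 191-292 aa range).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit, ProteinRecord

#: DNA-binding (HTH) domain classes accepted for the LuxR C-terminus.
DEFAULT_LUXR_DNA_DOMAINS = frozenset({"IPR000792", "IPR011991"})

#: Autoinducer/ligand-binding domain classes accepted for the LuxR N-terminus.
#: The published filter does not enumerate its ABD list; this default is a
#: reconstruction (autoinducer-binding, GAF-like, CheY-like superfamily and
#: response-regulator receiver domains) and should be overridden when the
#: exact set is known.
DEFAULT_LUXR_ABD_DOMAINS = frozenset(
    {"IPR005143", "IPR029016", "IPR011006", "IPR001789"}
)

DEFAULT_LUXI_DOMAINS = frozenset({"IPR001690"})


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class MiningConfig:
    """Domain sets and length windows for candidate selection."""

    luxi_domains: frozenset[str] = DEFAULT_LUXI_DOMAINS
    luxr_dna_domains: frozenset[str] = DEFAULT_LUXR_DNA_DOMAINS
    luxr_abd_domains: frozenset[str] = DEFAULT_LUXR_ABD_DOMAINS
    luxr_min_len: int = 200
    luxr_max_len: int = 300
    luxi_min_len: int = 150
    luxi_max_len: int = 350

    def __post_init__(self) -> None:
        if not self.luxi_domains or not self.luxr_dna_domains:
            raise MiningError("domain sets must be non-empty")
        if self.luxi_min_len >= self.luxi_max_len:
            raise MiningError("luxi_min_len must be < luxi_max_len")
        if self.luxr_min_len >= self.luxr_max_len:
            raise MiningError("luxr_min_len must be < luxr_max_len")


def _domains_by_protein(
    proteins: Sequence[ProteinRecord], hits: Iterable[DomainHit]
) -> dict[str, set[str]]:
    known = {p.id for p in proteins}
    orphans = sorted({h.protein_id for h in hits if h.protein_id not in known})
    if orphans:
        raise MiningError(
            f"domain hits reference unknown proteins: {orphans}"
        )
    by_protein: dict[str, set[str]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, set()).add(h.domain_id)
    return by_protein


def select_luxi(
    proteins: Sequence[ProteinRecord],
    hits: Iterable[DomainHit],
    cfg: MiningConfig | None = None,
) -> list[ProteinRecord]:
    """Proteins with an autoinducer-synthase domain hit and in-window length."""
    cfg = cfg or MiningConfig()
    by_protein = _domains_by_protein(proteins, hits)
    selected = [
        p
        for p in proteins
        if by_protein.get(p.id, set()) & cfg.luxi_domains
        and cfg.luxi_min_len <= len(p) <= cfg.luxi_max_len
    ]
    return sorted(selected, key=lambda p: p.id)


def select_luxr(
    proteins: Sequence[ProteinRecord],
    hits: Iterable[DomainHit],
    cfg: MiningConfig | None = None,
) -> list[ProteinRecord]:
    """Proteins carrying both a DNA-binding and an ABD-class domain hit.

    Refuses to run when the configured ABD set is empty: the two-domain rule
    would silently degenerate to the DNA-binding filter.
    """
    cfg = cfg or MiningConfig()
    if not cfg.luxr_abd_domains:
        raise MiningError(
            "luxr_abd_domains is empty; the LuxR filter requires an explicit "
            "autoinducer/ligand-binding domain set"
        )
    by_protein = _domains_by_protein(proteins, hits)
    selected = [
        p
        for p in proteins
        if by_protein.get(p.id, set()) & cfg.luxr_dna_domains
        and by_protein.get(p.id, set()) & cfg.luxr_abd_domains
        and cfg.luxr_min_len <= len(p) <= cfg.luxr_max_len
    ]
    return sorted(selected, key=lambda p: p.id)


@dataclass(frozen=True)
class DomainCensus:
    """Counts of per-protein domain combinations and per-domain occurrence."""

    combination_counts: Mapping[tuple[str, ...], int]
    domain_counts: Mapping[str, int]

    @property
    def n_unique_domains(self) -> int:
        return len(self.domain_counts)

    @property
    def n_combinations(self) -> int:
        return len(self.combination_counts)


def domain_architecture_census(hits: Iterable[DomainHit]) -> DomainCensus:
    """Tally unique per-protein domain sets and per-domain occurrence.

    A domain is counted once per protein regardless of how many hits it has
    (occurrence = number of proteins containing it); combinations are the
    sorted unique domain set of each protein.
    """
    by_protein: dict[str, set[str]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, set()).add(h.domain_id)
    combos = Counter(tuple(sorted(domains)) for domains in by_protein.values())
    per_domain = Counter(
        d for domains in by_protein.values() for d in domains
    )
    return DomainCensus(dict(combos), dict(per_domain))


def length_summary(proteins: Sequence[ProteinRecord]) -> dict[str, float]:
    """Min/mean/max residue lengths of a candidate set (empty set -> zeros)."""
    if not proteins:
        return {"n": 0, "min": 0, "mean": 0.0, "max": 0}
    lengths = [len(p) for p in proteins]
    return {
        "n": len(lengths),
        "min": min(lengths),
        "mean": sum(lengths) / len(lengths),
        "max": max(lengths),
    }
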