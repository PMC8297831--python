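"""ATPase calling from domain tables and from primary sequence.

Two independent evidence routes are supported: (i) domain-table mode keeps
domain hits whose name or accession contains an ATPase keyword ("ATP" or
"AAA" by default) at an e-value cutoff of 1e-3, and (ii) motif mode scans
the sequence itself for the Walker-A signature, with Walker-B reported as
supporting evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mobatp.motifs import (
    DEFAULT_WALKER_B_WINDOW,
    MotifHit,
    scan_walker_a,
    scan_walker_b,
)
from mobatp.records import DomainHit

DEFAULT_E_CUTOFF = 1e-3
DEFAULT_KEYWORDS = ("ATP", "AAA")


@dataclass
class AtpaseCall:
    """A protein called as an ATPase, with its supporting evidence."""

    protein_id: str
    n_atpase_domains: int
    evidence: str  # "domain_table", "motif" or "both"
    domain_hits: list[DomainHit] = field(default_factory=list)
    motif_hits: list[MotifHit] = field(default_factory=list)

    @property
    def is_multi(self) -> bool:
        return self.n_atpase_domains >= 2


def _keyword_match(hit: DomainHit, keywords: Sequence[str]) -> bool:
    name = hit.name.upper()
    acc = hit.accession.upper()
    return any(k.upper() in name or k.upper() in acc for k in keywords)


def call_atpase_domains(
    hits: Iterable[DomainHit],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> list[DomainHit]:
    """Keep hits with e_value <= cutoff and an ATPase keyword in name/accession.

    Keyword matching is a case-insensitive substring test; raising the cutoff
    never removes a qualifying hit.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    if not keywords:
        raise ValueError("keywords must be non-empty")
    return [h for h in hits if h.e_value <= e_cutoff and _keyword_match(h, keywords)]


def call_atpase_proteins(
    proteins: Mapping[str, str],
    hits: Iterable[DomainHit] = (),
    mode: str = "domain_table",
    e_cutoff: float = DEFAULT_E_CUTOFF,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    require_walker_b: bool = False,
    walker_b_window: tuple[int, int] = DEFAULT_WALKER_B_WINDOW,
) -> list[AtpaseCall]:
    """Call ATPase proteins in domain_table, motif, or both evidence modes.

    In domain_table mode a protein qualifies with >=1 qualifying domain hit
    and n_atpase_domains counts those hits. In motif mode a protein qualifies
    with >=1 Walker-A match (optionally also requiring a linked Walker-B when
    ``require_walker_b``) and n_atpase_domains counts Walker-A matches.
    ``both`` merges the two, preferring the domain-table count when present.
    Proteins with n_atpase_domains >= 2 form the "multiple ATPase" set.
    """
    if mode not in ("domain_table", "motif", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = list(hits)
    unknown = sorted({h.protein_id for h in hits} - set(proteins))
    if unknown:
        raise ValueError(f"domain hits reference unknown protein(s): {unknown[:5]}")

    by_protein: dict[str, list[DomainHit]] = {}
    if mode in ("domain_table", "both"):
        for h in call_atpase_domains(hits, e_cutoff=e_cutoff, keywords=keywords):
            by_protein.setdefault(h.protein_id, []).append(h)

    motif_by_protein: dict[str, list[MotifHit]] = {}
    if mode in ("motif", "both"):
        for pid, seq in proteins.items():
            if not seq:
                continue
            wa = scan_walker_a(seq, protein_id=pid)
            if not wa:
                continue
            support: list[MotifHit] = []
            for a in wa:
                support.extend(scan_walker_b(seq, a, window=walker_b_window))
            if require_walker_b and not support:
                continue
            motif_by_protein[pid] = wa + support

    calls = []
    for pid in sorted(set(by_protein) | set(motif_by_protein)):
        dom = by_protein.get(pid, [])
        mot = motif_by_protein.get(pid, [])
        if dom and mot:
            evidence = "both"
        elif dom:
            evidence = "domain_table"
        else:
            evidence = "motif"
        n = len(dom) if dom else sum(1 for m in mot if m.kind == "WalkerA")
        calls.append(
            AtpaseCall(
                protein_id=pid,
                n_atpase_domains=n,
                evidence=evidence,
                domain_hits=dom,
                motif_hits=mot,
            )
        )
    return calls


def annotation_keyword_search(
    annotations: Iterable[tuple[str, str]], keyword: str = "ATPase"
) -> list[str]:
    """Protein ids whose free-text annotation contains the keyword.

    Case-insensitive substring match, the first-pass census rule for
    annotation tables.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    kw = keyword.upper()
    return [pid for pid, text in annotations if text and kw in text.upper()]
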