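"""Walker-motif scanning of primary amino-acid sequence.

P-loop NTPases carry two diagnostic signatures: the ATP-binding Walker-A
motif, an alpha-helix followed by a glycine-rich loop with consensus
GxxGxGKT or GxxGxGKS (x = any residue), and the ATP-hydrolysis Walker-B
motif hhhhD (h = hydrophobic: V, I, L, F or M), a beta-strand that sits
roughly 100 residues downstream of the Walker-A in the folded domain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

#: hydrophobic residues admitted in the Walker-B signature
DEFAULT_HYDROPHOBIC = "VILFM"

#: default gap (in residues, measured from the Walker-A end to the Walker-B
#: start) within which a Walker-B is considered linked to its Walker-A; a
#: tolerant band around the canonical ~100-residue linker
DEFAULT_WALKER_B_WINDOW = (60, 140)

WALKER_A_LEN = 8
WALKER_B_LEN = 5

# lookahead so that overlapping windows are all reported
_WALKER_A_RE = re.compile(r"(?=(G..G.GK[TS]))")


@dataclass
class MotifHit:
    """A Walker-motif match on a protein sequence (1-based start)."""

    protein_id: str
    kind: str  # "WalkerA" or "WalkerB"
    position: int
    matched: str

    @property
    def end(self) -> int:
        """1-based inclusive end of the matched window."""
        return self.position + len(self.matched) - 1


def scan_walker_a(protein_seq: str, protein_id: str = "") -> list[MotifHit]:
    """Report every Walker-A window (GxxGxGK[T|S]) in ascending position.

    Overlapping matches are all reported. Positions are 1-based.
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    seq = protein_seq.upper()
    return [
        MotifHit(
            protein_id=protein_id,
            kind="WalkerA",
            position=m.start() + 1,
            matched=m.group(1),
        )
        for m in _WALKER_A_RE.finditer(seq)
    ]


def scan_walker_b(
    protein_seq: str,
    anchor: MotifHit,
    window: tuple[int, int] = DEFAULT_WALKER_B_WINDOW,
    hydrophobic: str = DEFAULT_HYDROPHOBIC,
    protein_id: str = "",
) -> list[MotifHit]:
    """Report Walker-B windows (hhhhD) downstream of a Walker-A anchor.

    A candidate qualifies when its 1-based start lies in
    ``[anchor.end + min_gap, anchor.end + max_gap]``.
    """
    min_gap, max_gap = window
    if min_gap > max_gap:
        raise ValueError(f"min_gap {min_gap} > max_gap {max_gap}")
    if anchor.kind != "WalkerA":
        raise ValueError("anchor must be a WalkerA hit")
    seq = protein_seq.upper()
    if seq[anchor.position - 1 : anchor.position - 1 + WALKER_A_LEN] != anchor.matched:
        raise ValueError("anchor does not match the sequence at its position")
    pattern = re.compile(f"(?=([{hydrophobic}]{{4}}D))")
    lo = anchor.end + min_gap
    hi = anchor.end + max_gap
    hits = []
    for m in pattern.finditer(seq):
        pos = m.start() + 1
        if lo <= pos <= hi:
            hits.append(
                MotifHit(
                    protein_id=protein_id or anchor.protein_id,
                    kind="WalkerB",
                    position=pos,
                    matched=m.group(1),
                )
            )
    return hits
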