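"""Long-range heavy-atom contacts and conformational-change scoring.

A residue pair is *in contact* when (a) the two residues are more than
``min_sequence_gap`` positions apart in the renumbered chain (long-range
only; gap exactly 5 does not qualify) and (b) some heavy-atom pair between
them is within ``heavy_atom_cutoff`` Angstrom (inclusive).  Per pair and
structure this gives a binary score.

The Average Contact Score (ACS) of a pair over a state group is the fraction
of the group's structures in which the pair is in contact.  At the
secondary-structure-element (SSE) level the per-structure score of an
element pair is the *count* of contacting residue pairs between the two
elements, and the SSE-ACS is its group mean.  The Conformational-Change
score is ``CC = ACS_closed - ACS_open``: positive means the contact favors
the closed state.

Only GCL-labeled residues participate; unlabeled residues are not
comparable across structures and are excluded entirely (they still count
for sequence gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .labels import GCLLabel, LabeledStructure, SSEKey

__all__ = [
    "ContactPolicy",
    "ScoreTable",
    "contact_map",
    "average_contact_scores",
    "sse_contact_scores",
    "sse_average_contact_scores",
    "conformational_change_scores",
]

LabelPair = tuple[GCLLabel, GCLLabel]
SSEPair = tuple[SSEKey, SSEKey]


@dataclass
class ContactPolicy:
    """Contact definition: heavy-atom cutoff (A) and minimal sequence gap.

    The cutoff is a standard heavy-atom contact threshold; it is echoed in
    every exported table so runs are comparable.  ``min_sequence_gap`` is
    exclusive: a contact requires gap > min_sequence_gap.
    """

    heavy_atom_cutoff: float = 4.5
    min_sequence_gap: int = 5

    def __post_init__(self) -> None:
        if self.heavy_atom_cutoff <= 0:
            raise ValueError("heavy_atom_cutoff must be > 0")
        if self.min_sequence_gap < 0:
            raise ValueError("min_sequence_gap must be >= 0")


def _ordered_label_pair(a: GCLLabel, b: GCLLabel) -> LabelPair:
    return (a, b) if a.sort_key <= b.sort_key else (b, a)


def _ordered_sse_pair(a: SSEKey, b: SSEKey) -> SSEPair:
    return (a, b) if a.sort_key <= b.sort_key else (b, a)


def contact_map(ls: LabeledStructure, policy: ContactPolicy | None = None) -> set[LabelPair]:
    """Set of unordered GCL label pairs in long-range heavy-atom contact."""
    policy = policy or ContactPolicy()
    coords = []
    atom_res: list[int] = []  # index into ls.residues
    for idx, lres in enumerate(ls.residues):
        if lres.label is None:
            continue
        res = ls.structure.residues[lres.chain_position - 1]
        xyz = res.heavy_coords()
        if xyz.size == 0:
            continue
        coords.append(xyz)
        atom_res.extend([idx] * len(xyz))
    if not coords:
        return set()
    xyz = np.vstack(coords)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(policy.heavy_atom_cutoff, output_type="ndarray")
    out: set[LabelPair] = set()
    for i, j in pairs:
        ri, rj = ls.residues[atom_res[i]], ls.residues[atom_res[j]]
        if ri is rj:
            continue
        if abs(ri.chain_position - rj.chain_position) <= policy.min_sequence_gap:
            continue
        out.add(_ordered_label_pair(ri.label, rj.label))
    return out


def average_contact_scores(
    group: Sequence[LabeledStructure], policy: ContactPolicy | None = None
) -> dict[LabelPair, float]:
    """Residue-level ACS over a state group.

    For each pair ever in contact in the group, ACS = (# structures with
    the contact) / (# structures).  Pairs never in contact are implicit
    zeros.  Raises on an empty group.
    """
    if not group:
        raise ValueError("empty state group")
    counts: dict[LabelPair, int] = {}
    for ls in group:
        for pair in contact_map(ls, policy):
            counts[pair] = counts.get(pair, 0) + 1
    n = len(group)
    return {pair: c / n for pair, c in counts.items()}


def sse_contact_scores(
    ls: LabeledStructure, policy: ContactPolicy | None = None
) -> dict[SSEPair, int]:
    """Element-level contact score: count of contacting residue pairs per SSE pair.

    Intra-element pairs (E == E) are counted when the residue pair passes
    the sequence-gap filter.
    """
    scores: dict[SSEPair, int] = {}
    for la, lb in contact_map(ls, policy):
        key = _ordered_sse_pair(la.sse, lb.sse)
        scores[key] = scores.get(key, 0) + 1
    return scores


def sse_average_contact_scores(
    group: Sequence[LabeledStructure], policy: ContactPolicy | None = None
) -> dict[SSEPair, float]:
    """SSE-ACS: group mean of the per-structure element-pair contact counts."""
    if not group:
        raise ValueError("empty state group")
    totals: dict[SSEPair, float] = {}
    for ls in group:
        for key, score in sse_contact_scores(ls, policy).items():
            totals[key] = totals.get(key, 0.0) + score
    n = len(group)
    return {key: total / n for key, total in totals.items()}


@dataclass
class ScoreTable:
    """ACS per state group plus CC scores at one level ('residue' or 'sse').

    ``pairs`` holds every pair observed in contact in either group; a pair
    with ``cc == 0`` is retained and flagged "no change".
    """

    level: str  # 'residue' | 'sse'
    acs_closed: dict
    acs_open: dict

    def __post_init__(self) -> None:
        if self.level not in ("residue", "sse"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def pairs(self) -> list:
        keys = set(self.acs_closed) | set(self.acs_open)
        return sorted(keys, key=lambda p: (p[0].sort_key, p[1].sort_key))

    def cc(self, pair) -> float:
        return self.acs_closed.get(pair, 0.0) - self.acs_open.get(pair, 0.0)

    def cc_scores(self) -> dict:
        return {pair: self.cc(pair) for pair in self.pairs}

    def no_change(self, pair) -> bool:
        return self.cc(pair) == 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            rows.append(
                {
                    "level": self.level,
                    "label_i": str(pair[0]),
                    "label_j": str(pair[1]),
                    "acs_closed": self.acs_closed.get(pair, 0.0),
                    "acs_open": self.acs_open.get(pair, 0.0),
                    "cc": self.cc(pair),
                }
            )
        return pd.DataFrame(
            rows, columns=["level", "label_i", "label_j", "acs_closed", "acs_open", "cc"]
        )


def conformational_change_scores(
    closed: Sequence[LabeledStructure],
    open_: Sequence[LabeledStructure],
    policy: ContactPolicy | None = None,
    level: str = "residue",
) -> ScoreTable:
    """CC score table from a closed and an open state group at one level."""
    if not closed or not open_:
        raise ValueError("empty state group")
    if level == "residue":
        acs_c = average_contact_scores(closed, policy)
        acs_o = average_contact_scores(open_, policy)
    elif level == "sse":
        acs_c = sse_average_contact_scores(closed, policy)
        acs_o = sse_average_contact_scores(open_, policy)
    else:
        raise ValueError(f"unknown level {level!r}")
    return ScoreTable(level=level, acs_closed=acs_c, acs_open=acs_o)
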