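"""Closed/open state classification from the RH.H4H5 <-> KD.HK ionic lock.

GRK structures are called *closed* when the minimal heavy-atom distance
between the bottom loop of the RH domain (RH.H4H5) and the bottom helix of
the kinase domain (KD.HK) is under 3.3 A, *open* when it is over 5.0 A, and
*intermediate* otherwise.  Intermediate structures keep their state call but
are excluded from closed/open group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .labels import GCLLabel, LabeledResidue, LabeledStructure, SSEKey

__all__ = [
    "CLOSED",
    "OPEN",
    "INTERMEDIATE",
    "StateThresholds",
    "StateCall",
    "min_region_distance",
    "classify_state",
    "lock_contact_pair",
]

CLOSED = "closed"
OPEN = "open"
INTERMEDIATE = "intermediate"


@dataclass
class StateThresholds:
    """Distance thresholds (Angstrom) defining the closed/open classification.

    Boundary equalities (exactly ``closed_max`` or ``open_min``) classify as
    intermediate: the criteria are strictly "under" and "over".
    """

    closed_max: float = 3.3
    open_min: float = 5.0
    region_a: SSEKey = field(default_factory=lambda: SSEKey("RH", "H4H5"))
    region_b: SSEKey = field(default_factory=lambda: SSEKey("KD", "HK"))

    def __post_init__(self) -> None:
        if not 0 < self.closed_max < self.open_min:
            raise ValueError("require 0 < closed_max < open_min")


@dataclass
class StateCall:
    structure_id: str
    distance: float
    state: str
    closest_pair: tuple[GCLLabel, str, GCLLabel, str]  # label_a, resname_a, label_b, resname_b


def _region_atoms(
    ls: LabeledStructure, key: SSEKey
) -> tuple[np.ndarray, list[LabeledResidue]]:
    """Stack heavy-atom coordinates for a region; owners[i] = residue of atom i."""
    coords = []
    owners: list[LabeledResidue] = []
    for lres in ls.sse_members(key):
        res = ls.structure.residues[lres.chain_position - 1]
        xyz = res.heavy_coords()
        if xyz.size == 0:
            continue
        coords.append(xyz)
        owners.extend([lres] * len(xyz))
    if not coords:
        raise ValueError(
            f"{ls.structure_id}: region {key} has no labeled residues with heavy atoms"
        )
    return np.vstack(coords), owners


def min_region_distance(
    ls: LabeledStructure, a: SSEKey, b: SSEKey
) -> tuple[float, tuple[GCLLabel, str, GCLLabel, str]]:
    """Minimum heavy-atom distance between two labeled regions.

    Returns the distance and the residue pair achieving it, as
    ``(label_a, resname_a, label_b, resname_b)`` following the argument
    order.  Exact distance ties are broken by lexicographic label order.
    """
    xyz_a, owners_a = _region_atoms(ls, a)
    xyz_b, owners_b = _region_atoms(ls, b)
    dmat = cdist(xyz_a, xyz_b)
    dmin = float(dmat.min())
    ii, jj = np.nonzero(dmat <= dmin + 1e-12)
    candidates = sorted(
        (owners_a[i].label.sort_key, owners_b[j].label.sort_key, i, j)
        for i, j in zip(ii, jj)
    )
    _, _, i, j = candidates[0]
    ra, rb = owners_a[i], owners_b[j]
    return dmin, (ra.label, ra.residue_name, rb.label, rb.residue_name)


def classify_state(distance: float, thresholds: StateThresholds | None = None) -> str:
    """Map an ionic-lock distance to closed / open / intermediate."""
    thresholds = thresholds or StateThresholds()
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance < thresholds.closed_max:
        return CLOSED
    if distance > thresholds.open_min:
        return OPEN
    return INTERMEDIATE


def lock_contact_pair(
    ls: LabeledStructure, thresholds: StateThresholds | None = None
) -> StateCall:
    """Full state call for one structure: lock distance, state, closest pair."""
    thresholds = thresholds or StateThresholds()
    distance, pair = min_region_distance(ls, thresholds.region_a, thresholds.region_b)
    return StateCall(
        structure_id=ls.structure_id,
        distance=distance,
        state=classify_state(distance, thresholds),
        closest_pair=pair,
    )
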