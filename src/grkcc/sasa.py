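"""Shrake-Rupley solvent-accessible surface area and state-wise rSASA.

Each heavy atom is expanded by the probe radius (default 1.4 A, water) and
sampled with a deterministic golden-spiral point lattice; a sample point is
accessible when it lies outside every other atom's expanded sphere.  The
atom's SASA is its accessible fraction times the expanded-sphere area;
residue SASA sums its atoms.  Relative SASA (rSASA) normalizes by a
residue-type maximum accessible area (Tien et al. theoretical values) and
is clamped to [0, 1.2].

Hydrogens are excluded throughout, consistent with the heavy-atom contact
conventions of the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .labels import GCLLabel, LabeledStructure
from .structures import StructureModel

__all__ = [
    "VDW_RADII",
    "MAX_ACCESSIBLE_AREA",
    "SasaPolicy",
    "SasaResult",
    "shrake_rupley_sasa",
    "relative_sasa_by_state",
]

# Van der Waals radii (A) for common protein heavy elements.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# Theoretical maximum accessible surface areas per residue type (A^2),
# Tien et al. 2013.
MAX_ACCESSIBLE_AREA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class SasaPolicy:
    probe_radius: float = 1.4
    sphere_points: int = 960
    radius_table: Mapping[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    reference_max: Mapping[str, float] = field(
        default_factory=lambda: dict(MAX_ACCESSIBLE_AREA)
    )

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.sphere_points < 92:
            raise ValueError("sphere_points must be >= 92")
        if any(r <= 0 for r in self.radius_table.values()):
            raise ValueError("van der Waals radii must be positive")


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom: np.ndarray  # A^2, aligned with the flattened heavy-atom list
    per_residue: dict[int, float]  # residue index in model.residues -> A^2

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def shrake_rupley_sasa(model: StructureModel, policy: SasaPolicy | None = None) -> SasaResult:
    """Per-atom and per-residue SASA (A^2) for all heavy atoms of a structure.

    Raises ``KeyError``-style ``ValueError`` listing any element missing
    from the radius table.
    """
    policy = policy or SasaPolicy()
    coords: list[list[float]] = []
    radii: list[float] = []
    atom_residue: list[int] = []
    unknown: set[str] = set()
    for ridx, res in enumerate(model.residues):
        for atom in res.heavy_atoms():
            r = policy.radius_table.get(atom.element)
            if r is None:
                unknown.add(atom.element)
                continue
            coords.append([atom.x, atom.y, atom.z])
            radii.append(r + policy.probe_radius)
            atom_residue.append(ridx)
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {sorted(unknown)}")
    if not coords:
        return SasaResult(per_atom=np.empty(0), per_residue={})

    xyz = np.asarray(coords)
    rr = np.asarray(radii)
    tree = cKDTree(xyz)
    unit = _sphere_lattice(policy.sphere_points)
    max_r = rr.max()

    per_atom = np.empty(len(xyz))
    for i in range(len(xyz)):
        neighbors = [
            j for j in tree.query_ball_point(xyz[i], rr[i] + max_r) if j != i
        ]
        pts = xyz[i] + rr[i] * unit
        if neighbors:
            nxyz = xyz[neighbors]
            nr = rr[neighbors]
            # point buried if inside any neighbor's expanded sphere
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * math.pi * rr[i] ** 2

    per_residue: dict[int, float] = {}
    for area, ridx in zip(per_atom, atom_residue):
        per_residue[ridx] = per_residue.get(ridx, 0.0) + float(area)
    return SasaResult(per_atom=per_atom, per_residue=per_residue)


def relative_sasa_by_state(
    closed: Sequence[LabeledStructure],
    open_: Sequence[LabeledStructure],
    positions: Iterable[GCLLabel],
    policy: SasaPolicy | None = None,
) -> pd.DataFrame:
    """Mean rSASA per GCL position in closed vs open groups, with difference.

    rSASA = residue SASA / reference maximum for its residue type, clamped
    to [0, 1.2].  A structure missing a position is skipped for that
    position (logged in the ``n_closed``/``n_open`` columns).  A residue
    type absent from the reference table raises.
    """
    policy = policy or SasaPolicy()
    positions = sorted(set(positions), key=lambda l: l.sort_key)

    def group_values(group: Sequence[LabeledStructure]) -> dict[GCLLabel, list[float]]:
        values: dict[GCLLabel, list[float]] = {p: [] for p in positions}
        for ls in group:
            result = shrake_rupley_sasa(ls.structure, policy)
            lmap = ls.label_map()
            for pos in positions:
                lres = lmap.get(pos)
                if lres is None:
                    continue
                ridx = lres.chain_position - 1
                resname = ls.structure.residues[ridx].name
                ref = policy.reference_max.get(resname)
                if ref is None:
                    raise ValueError(f"no reference max area for residue type {resname}")
                rsasa = min(result.per_residue.get(ridx, 0.0) / ref, 1.2)
                values[pos].append(max(rsasa, 0.0))
        return values

    vc = group_values(closed)
    vo = group_values(open_)
    rows = []
    for pos in positions:
        mc = float(np.mean(vc[pos])) if vc[pos] else float("nan")
        mo = float(np.mean(vo[pos])) if vo[pos] else float("nan")
        rows.append(
            {
                "gcl_label": str(pos),
                "mean_rsasa_closed": mc,
                "mean_rsasa_open": mo,
                "difference": mc - mo,
                "n_closed": len(vc[pos]),
                "n_open": len(vo[pos]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gcl_label",
            "mean_rsasa_closed",
            "mean_rsasa_open",
            "difference",
            "n_closed",
            "n_open",
        ],
    )
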