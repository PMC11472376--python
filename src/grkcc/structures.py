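"""PDB reading, chain splitting/renumbering, and resolution/fragment filters.

Mirrors a common preprocessing recipe for structure-ensemble analyses: every
chain of every deposited entry becomes an independent, sequentially
renumbered structure; entries worse than a resolution cutoff and chains
covering too little of the label table ("short fragments") are dropped.

Parsing is delegated to :mod:`gemmi`; this module owns the in-memory
container and the filtering policy.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "FilterPolicy",
    "DroppedStructure",
    "StructureError",
    "read_structures",
    "split_and_renumber_chains",
    "filter_structures",
    "to_pdb_string",
    "write_structure",
]


class StructureError(ValueError):
    """Raised for unreadable files or structures without polymer atoms."""


@dataclass
class Atom:
    name: str
    element: str  # element symbol, upper case ("C", "N", "O", "S", ...)
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    number: int            # current (possibly renumbered) residue number
    name: str              # 3-letter code
    atoms: list[Atom]
    author_number: int | None = None  # original deposited numbering
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.author_number is None:
            self.author_number = self.number

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            return np.empty((0, 3))
        return np.array([[a.x, a.y, a.z] for a in heavy])


@dataclass
class StructureModel:
    """One polymer chain with metadata; coordinates in Angstrom."""

    pdb_code: str
    chain_id: str
    resolution: float | None  # Angstrom; None = unknown
    residues: list[Residue] = field(default_factory=list)

    @property
    def structure_id(self) -> str:
        return f"{self.pdb_code}_{self.chain_id}"

    def heavy_atom_count(self) -> int:
        return sum(len(r.heavy_atoms()) for r in self.residues)

    def all_heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues if r.heavy_atoms()]
        if not parts:
            return np.empty((0, 3))
        return np.vstack(parts)


@dataclass
class FilterPolicy:
    """Resolution and fragment filters applied before scoring.

    ``min_label_coverage`` operationalizes "short fragment": a chain mapping
    fewer than this fraction of the subtype's label table is dropped.
    """

    max_resolution: float = 4.00
    min_label_coverage: float = 0.50
    exclude_unknown_resolution: bool = True

    def __post_init__(self) -> None:
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be > 0")
        if not 0.0 <= self.min_label_coverage <= 1.0:
            raise ValueError("min_label_coverage must be in [0, 1]")


@dataclass
class DroppedStructure:
    model: StructureModel
    reason: str  # "resolution" | "unknown_resolution" | "fragment"
    detail: str = ""


def _select_altloc(atoms: list[Atom]) -> list[Atom]:
    # Keep the highest-occupancy conformer per atom name; ties prefer
    # altloc 'A', then first encountered.
    by_name: dict[str, Atom] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if atom.occupancy > prev.occupancy or (
            atom.occupancy == prev.occupancy
            and atom.altloc == "A"
            and prev.altloc != "A"
        ):
            by_name[atom.name] = atom
    kept = list(by_name.values())
    for a in kept:
        a.altloc = ""
    return kept


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    # Standard amino acids, plus modified amino acids that carry a CA atom.
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_water():
        return False
    if info is not None and info.is_amino_acid():
        return True
    return res.find_atom("CA", "*") is not None and len(res) > 1


def read_structures(path: str | Path) -> list[StructureModel]:
    """Read a PDB file, returning one :class:`StructureModel` per chain.

    Resolution comes from the header (REMARK 2) when present, else ``None``.
    Only polymer residues are kept; for alternate locations the
    highest-occupancy conformer survives.  Raises :class:`StructureError`
    on unreadable input or if no polymer atoms are found.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from None
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    # Prefer the 4-character id from the HEADER record; fall back to the stem.
    header_id = (st.name or "").strip()
    pdb_code = header_id.upper() if len(header_id) == 4 else path.stem.upper()

    models: list[StructureModel] = []
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not _is_polymer_residue(res):
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    x=a.pos.x,
                    y=a.pos.y,
                    z=a.pos.z,
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc else "",
                )
                for a in res
            ]
            atoms = _select_altloc(atoms)
            for atom in atoms:
                if not all(math.isfinite(v) for v in (atom.x, atom.y, atom.z)):
                    raise StructureError(
                        f"{path}: non-finite coordinate in {chain.name}/{res.seqid.num}"
                    )
            residues.append(
                Residue(
                    number=res.seqid.num,
                    name=res.name.strip().upper(),
                    atoms=atoms,
                    author_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                )
            )
        if residues:
            models.append(
                StructureModel(
                    pdb_code=pdb_code,
                    chain_id=chain.name,
                    resolution=resolution,
                    residues=residues,
                )
            )
    if not models:
        raise StructureError(f"{path}: no polymer atoms found")
    return models


def split_and_renumber_chains(models: Iterable[StructureModel]) -> list[StructureModel]:
    """Renumber each chain sequentially from 1, keeping author numbering.

    Atom counts and coordinates are preserved exactly; only residue
    numbering changes.  Empty input yields empty output.
    """
    out: list[StructureModel] = []
    for model in models:
        residues = [
            replace(
                copy.deepcopy(res),
                number=i,
                author_number=res.author_number,
            )
            for i, res in enumerate(model.residues, start=1)
        ]
        out.append(
            StructureModel(
                pdb_code=model.pdb_code,
                chain_id=model.chain_id,
                resolution=model.resolution,
                residues=residues,
            )
        )
    return out


def filter_structures(
    models: Sequence[StructureModel],
    labeled_coverage: Sequence[float],
    policy: FilterPolicy | None = None,
) -> tuple[list[StructureModel], list[DroppedStructure]]:
    """Partition ``models`` into kept and dropped under ``policy``.

    Drops: resolution strictly above ``max_resolution``; unknown resolution
    if the policy excludes it; label coverage below ``min_label_coverage``
    ("fragment").  A resolution of exactly the cutoff is kept.
    """
    policy = policy or FilterPolicy()
    if len(models) != len(labeled_coverage):
        raise ValueError("labeled_coverage must align with models")
    kept: list[StructureModel] = []
    dropped: list[DroppedStructure] = []
    for model, coverage in zip(models, labeled_coverage):
        if model.resolution is None:
            if policy.exclude_unknown_resolution:
                dropped.append(
                    DroppedStructure(model, "unknown_resolution", "no REMARK 2 record")
                )
                continue
        elif model.resolution > policy.max_resolution:
            dropped.append(
                DroppedStructure(
                    model,
                    "resolution",
                    f"{model.resolution:.2f} A > {policy.max_resolution:.2f} A",
                )
            )
            continue
        if coverage < policy.min_label_coverage:
            dropped.append(
                DroppedStructure(
                    model,
                    "fragment",
                    f"label coverage {coverage:.2f} < {policy.min_label_coverage:.2f}",
                )
            )
            continue
        kept.append(model)
    return kept, dropped


def to_pdb_string(model: StructureModel) -> str:
    """Serialize a StructureModel as minimal PDB text (REMARK 2 + ATOM records)."""
    lines = []
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    serial = 1
    chain = (model.chain_id or "A")[:1]
    for res in model.residues:
        for a in res.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {res.name:>3s} {chain}{res.number:4d}"
                f"    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}  0.00"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(model: StructureModel, path: str | Path) -> None:
    Path(path).write_text(to_pdb_string(model))
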