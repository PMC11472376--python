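"""Synthetic GRK-like structure families and alignments with planted truth.

The generator exists so every pipeline stage is exercisable without
downloads.  Realism is explicitly not a goal: residues are short rigid
atom stacks (N, CA, C, O at fixed vertical offsets) placed on a coarse
scaffold in which only the distance relations the pipeline consumes are
controlled:

* non-planted long-range residue pairs sit >= 8 A apart (never contacts);
* the two lock regions (RH.H4H5 / KD.HK by default) are placed so that
  their minimal heavy-atom distance equals the requested closed or open
  lock distance, achieved by one designated residue pair;
* each planted contact pair is moved to an isolated meeting site, 3.5 A
  apart in the state group(s) where the contact should exist and 20 A
  apart otherwise.

Default family sizes mirror the study conditions: GRK2/3 with 7 closed +
3 open chains and GRK4/5/6 with 6 closed + 2 open.  Alignments plant
invariant (fully conserved) columns against a mutating background across
37 vertebrate-like species per subtype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import GCLEntry, GCLLabel, GCLTable, SSEKey
from .structures import Atom, Residue, StructureModel, to_pdb_string
from .conservation import SequenceSet

__all__ = [
    "DEFAULT_LAYOUT",
    "SubfamilySpec",
    "PlantedChange",
    "FamilySpec",
    "FamilyData",
    "MsaSpec",
    "MsaData",
    "generate_family",
    "generate_msa",
]

# (element, length) in sequence order; lock regions RH.H4H5 and KD.HK included.
DEFAULT_LAYOUT: tuple[tuple[SSEKey, int], ...] = (
    (SSEKey("RH", "H1"), 4),
    (SSEKey("RH", "H4H5"), 3),
    (SSEKey("RH", "H6"), 4),
    (SSEKey("KD", "S1"), 4),
    (SSEKey("KD", "HK"), 6),
    (SSEKey("KD", "HKHL"), 6),
)

_RESIDUE_CYCLE = (
    "ALA", "LEU", "SER", "GLY", "THR", "PHE", "LYS", "ASP",
    "ILE", "GLU", "ASN", "TYR", "PRO", "MET", "GLN", "TRP",
)

_ATOM_STACK = (("N", "N", 0.0), ("CA", "C", 0.5), ("C", "C", 1.0), ("O", "O", 1.5))

_SPACING = 8.0       # A between scaffold home points; > any contact cutoff in use
_CONTACT_DIST = 3.5  # A separation of a planted pair when in contact
_APART_DIST = 20.0   # A separation of a planted pair when not in contact


@dataclass
class SubfamilySpec:
    name: str
    n_closed: int
    n_open: int


@dataclass(frozen=True)
class PlantedChange:
    pair: tuple[GCLLabel, GCLLabel]
    present_in: str  # 'closed_only' | 'open_only' | 'both'


def _default_subfamilies() -> list[SubfamilySpec]:
    return [SubfamilySpec("GRK23", 7, 3), SubfamilySpec("GRK456", 6, 2)]


def _default_planted() -> list[PlantedChange]:
    return [
        PlantedChange((GCLLabel("RH", "H1", 1), GCLLabel("KD", "S1", 2)), "closed_only"),
        PlantedChange((GCLLabel("RH", "H6", 2), GCLLabel("KD", "HKHL", 4)), "open_only"),
        PlantedChange((GCLLabel("RH", "H1", 3), GCLLabel("KD", "HKHL", 6)), "both"),
    ]


@dataclass
class FamilySpec:
    subfamilies: list[SubfamilySpec] = field(default_factory=_default_subfamilies)
    layout: tuple[tuple[SSEKey, int], ...] = DEFAULT_LAYOUT
    lock_distance_closed: float = 2.8
    lock_distance_open: float = 6.5
    lock_region_a: SSEKey = field(default_factory=lambda: SSEKey("RH", "H4H5"))
    lock_region_b: SSEKey = field(default_factory=lambda: SSEKey("KD", "HK"))
    lock_pair_indices: tuple[int, int] = (2, 3)  # element indices of the closest pair
    planted_changes: list[PlantedChange] = field(default_factory=_default_planted)
    coordinate_noise: float = 0.0  # A, gaussian per coordinate
    resolution: float = 2.5
    contact_cutoff: float = 4.5    # must match the scoring policy in use
    min_sequence_gap: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lock_distance_closed < 3.3:
            raise ValueError("lock_distance_closed must be < 3.3 A")
        if not self.lock_distance_open > 5.0:
            raise ValueError("lock_distance_open must be > 5.0 A")

    # -- derived layout helpers -------------------------------------------

    def positions(self) -> list[tuple[int, GCLLabel]]:
        """1-based sequence position and label for every layout residue."""
        out = []
        pos = 0
        for sse, length in self.layout:
            for idx in range(1, length + 1):
                pos += 1
                out.append((pos, GCLLabel(sse.domain, sse.element, idx)))
        return out

    def label_positions(self) -> dict[GCLLabel, int]:
        return {label: pos for pos, label in self.positions()}

    def validate_geometry(self) -> None:
        lp = self.label_positions()
        lock_elements = {self.lock_region_a, self.lock_region_b}
        for i, lock in enumerate(self.lock_pair_indices):
            region = (self.lock_region_a, self.lock_region_b)[i]
            if GCLLabel(region.domain, region.element, lock) not in lp:
                raise ValueError(f"infeasible geometry: lock index {lock} outside {region}")
        used: set[GCLLabel] = set()
        for change in self.planted_changes:
            a, b = change.pair
            for lab in (a, b):
                if lab not in lp:
                    raise ValueError(f"infeasible geometry: planted label {lab} not in layout")
                if lab.sse in lock_elements:
                    raise ValueError(
                        f"infeasible geometry: planted contact {a}-{b} conflicts with "
                        f"the lock region {lab.sse}"
                    )
                if lab in used:
                    raise ValueError(
                        f"infeasible geometry: residue {lab} appears in multiple planted pairs"
                    )
                used.add(lab)
            if abs(lp[a] - lp[b]) <= self.min_sequence_gap:
                raise ValueError(
                    f"infeasible geometry: planted pair {a}-{b} violates the "
                    f"sequence-gap rule (gap {abs(lp[a] - lp[b])})"
                )
            if change.present_in not in ("closed_only", "open_only", "both"):
                raise ValueError(f"unknown present_in {change.present_in!r}")


@dataclass
class FamilyData:
    pdb_texts: dict[str, str]            # structure id -> PDB file content
    tables: dict[str, GCLTable]          # subfamily -> label table
    truth: dict                          # expected states, CC values, network

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Materialize PDB files, TSV tables and the JSON truth record."""
        from .labels import write_gcl_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid, text in self.pdb_texts.items():
            p = outdir / f"{sid}.pdb"
            p.write_text(text)
            paths[sid] = p
        for subfamily, table in self.tables.items():
            p = outdir / f"gcl_table_{subfamily}.tsv"
            with open(p, "w") as fh:
                write_gcl_table(table, fh)
            paths[f"table_{subfamily}"] = p
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        paths["truth"] = truth_path
        return paths


def _pair_key(a: GCLLabel, b: GCLLabel) -> str:
    first, second = sorted((a, b), key=lambda l: l.sort_key)
    return f"{first}|{second}"


def _home_points(spec: FamilySpec) -> dict[GCLLabel, np.ndarray]:
    """Scaffold home point (x, y) per residue, before state-dependent moves."""
    points: dict[GCLLabel, np.ndarray] = {}
    for pos, label in spec.positions():
        points[label] = np.array([_SPACING * (pos - 1), 0.0])
    # lock regions on their own rows; the designated pair shares an x column
    a_members = [l for _, l in spec.positions() if l.sse == spec.lock_region_a]
    b_members = [l for _, l in spec.positions() if l.sse == spec.lock_region_b]
    ia, ib = spec.lock_pair_indices
    for l in a_members:
        points[l] = np.array([_SPACING * l.index, -60.0])
    x_align = _SPACING * ia
    for l in b_members:
        points[l] = np.array([x_align + _SPACING * (l.index - ib), 0.0])  # y set below
    return points


def _structure_coords(spec: FamilySpec, state: str) -> dict[GCLLabel, np.ndarray]:
    """Final (x, y) home point per residue for one structure of a given state."""
    points = _home_points(spec)
    lock_d = spec.lock_distance_closed if state == "closed" else spec.lock_distance_open
    ia, ib = spec.lock_pair_indices
    b_members = [l for l in points if l.sse == spec.lock_region_b]
    for l in b_members:
        extra = 0.0 if l.index == ib else 4.0
        points[l] = np.array([points[l][0], -60.0 - lock_d - extra])
    for site, change in enumerate(spec.planted_changes):
        a, b = change.pair
        in_contact = change.present_in == "both" or (
            change.present_in == "closed_only" and state == "closed"
        ) or (change.present_in == "open_only" and state == "open")
        y_site = 60.0 + 25.0 * site
        sep = _CONTACT_DIST if in_contact else _APART_DIST
        points[a] = np.array([0.0, y_site])
        points[b] = np.array([sep, y_site])
    return points


def _residue_names(spec: FamilySpec) -> dict[GCLLabel, str]:
    names = {}
    ia, ib = spec.lock_pair_indices
    lock_a = GCLLabel(spec.lock_region_a.domain, spec.lock_region_a.element, ia)
    lock_b = GCLLabel(spec.lock_region_b.domain, spec.lock_region_b.element, ib)
    for pos, label in spec.positions():
        if label == lock_a:
            names[label] = "VAL"
        elif label == lock_b:
            names[label] = "ARG"
        else:
            names[label] = _RESIDUE_CYCLE[(pos - 1) % len(_RESIDUE_CYCLE)]
    return names


def _build_model(
    spec: FamilySpec,
    sid: str,
    state: str,
    rng: np.random.Generator,
) -> StructureModel:
    points = _structure_coords(spec, state)
    names = _residue_names(spec)
    residues = []
    for pos, label in spec.positions():
        x, y = points[label]
        atoms = []
        for name, element, dz in _ATOM_STACK:
            noise = (
                rng.normal(0.0, spec.coordinate_noise, size=3)
                if spec.coordinate_noise > 0
                else np.zeros(3)
            )
            atoms.append(
                Atom(
                    name=name,
                    element=element,
                    x=float(x + noise[0]),
                    y=float(y + noise[1]),
                    z=float(dz + noise[2]),
                )
            )
        residues.append(Residue(number=pos, name=names[label], atoms=atoms))
    return StructureModel(
        pdb_code=sid, chain_id="A", resolution=spec.resolution, residues=residues
    )


def _expected_cc(spec: FamilySpec) -> dict[str, float]:
    """Planted truth at residue level: pair key -> expected CC (zero-noise)."""
    cc: dict[str, float] = {}
    ia, ib = spec.lock_pair_indices
    lock_a = GCLLabel(spec.lock_region_a.domain, spec.lock_region_a.element, ia)
    lock_b = GCLLabel(spec.lock_region_b.domain, spec.lock_region_b.element, ib)
    # the designated lock pair is a contact exactly when closed (if within cutoff)
    lock_cc = 0.0
    if spec.lock_distance_closed <= spec.contact_cutoff:
        lock_cc += 1.0
    if spec.lock_distance_open <= spec.contact_cutoff:
        lock_cc -= 1.0
    if lock_cc != 0.0 or spec.lock_distance_closed <= spec.contact_cutoff:
        cc[_pair_key(lock_a, lock_b)] = lock_cc
    for change in spec.planted_changes:
        a, b = change.pair
        value = {"closed_only": 1.0, "open_only": -1.0, "both": 0.0}[change.present_in]
        cc[_pair_key(a, b)] = value
    return cc


def generate_family(spec: FamilySpec | None = None) -> FamilyData:
    """Generate a toy structure family with planted truth.

    Deterministic: the same spec and seed yield byte-identical PDB text.
    Raises on an infeasible geometry (planted pair in a lock region,
    sequence-gap violation, residue reuse).
    """
    spec = spec or FamilySpec()
    spec.validate_geometry()
    rng = np.random.default_rng(spec.seed)

    pdb_texts: dict[str, str] = {}
    tables: dict[str, GCLTable] = {}
    structures_truth = []
    ia, ib = spec.lock_pair_indices
    lock_a = GCLLabel(spec.lock_region_a.domain, spec.lock_region_a.element, ia)
    lock_b = GCLLabel(spec.lock_region_b.domain, spec.lock_region_b.element, ib)

    names = _residue_names(spec)
    entries = [
        GCLEntry(residue_number=pos, residue_name=names[label], label=label)
        for pos, label in spec.positions()
    ]
    for subfamily in spec.subfamilies:
        tables[subfamily.name] = GCLTable(subtype=subfamily.name, entries=list(entries))
        for state, count in (("closed", subfamily.n_closed), ("open", subfamily.n_open)):
            for i in range(1, count + 1):
                # upper-case id so it survives PDB-code normalization on re-read
                sid = f"{subfamily.name}_{state}{i}".upper()
                model = _build_model(spec, sid, state, rng)
                pdb_texts[sid] = to_pdb_string(model)
                structures_truth.append(
                    {
                        "id": f"{sid}_A",
                        "subfamily": subfamily.name,
                        "state": state,
                        "lock_distance": (
                            spec.lock_distance_closed
                            if state == "closed"
                            else spec.lock_distance_open
                        ),
                        "closest_pair": [str(lock_a), str(lock_b)],
                    }
                )

    cc = _expected_cc(spec)
    n_subfamilies = len(spec.subfamilies)
    network_edges = [
        {"pair": key, "weight": value * n_subfamilies}
        for key, value in sorted(cc.items())
        if abs(value * n_subfamilies) > 1.0
    ]
    truth = {
        "seed": spec.seed,
        "structures": structures_truth,
        "expected_cc": cc,
        "expected_network_edges": network_edges,
        "contact_cutoff": spec.contact_cutoff,
    }
    return FamilyData(pdb_texts=pdb_texts, tables=tables, truth=truth)


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class MsaSpec:
    subtypes: tuple[str, ...] = tuple(f"GRK{i}" for i in range(1, 8))
    n_species: int = 37
    layout: tuple[tuple[SSEKey, int], ...] = DEFAULT_LAYOUT
    planted_labels: tuple[GCLLabel, ...] = (
        GCLLabel("RH", "H4H5", 1),
        GCLLabel("RH", "H4H5", 2),
        GCLLabel("RH", "H4H5", 3),
        GCLLabel("KD", "HK", 2),
        GCLLabel("KD", "HK", 3),
        GCLLabel("KD", "HKHL", 1),
        GCLLabel("KD", "HKHL", 4),
        GCLLabel("KD", "S1", 3),
    )
    background_rate: float = 0.5  # per-sequence substitution probability
    reference_species: str = "Homo_sapiens"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        labels = {label for _, label in _layout_positions(self.layout)}
        missing = [str(l) for l in self.planted_labels if l not in labels]
        if missing:
            raise ValueError(f"planted labels outside layout: {missing}")


def _layout_positions(layout) -> list[tuple[int, GCLLabel]]:
    out, pos = [], 0
    for sse, length in layout:
        for idx in range(1, length + 1):
            pos += 1
            out.append((pos, GCLLabel(sse.domain, sse.element, idx)))
    return out


_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class MsaData:
    sets: dict[str, SequenceSet]     # subtype -> aligned sequences
    table: GCLTable                  # reference residue number -> label
    reference_lengths: dict[str, int]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .conservation import write_fasta
        from .labels import write_gcl_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for subtype, sset in self.sets.items():
            p = outdir / f"msa_{subtype}.fasta"
            write_fasta(sset, p)
            paths[subtype] = p
        p = outdir / "gcl_table_reference.tsv"
        with open(p, "w") as fh:
            write_gcl_table(self.table, fh)
        paths["table"] = p
        tp = outdir / "msa_truth.json"
        tp.write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        paths["truth"] = tp
        return paths


def generate_msa(spec: MsaSpec | None = None) -> MsaData:
    """Generate per-subtype alignments with planted invariant columns.

    Planted columns are identical across all species (conservation 11);
    background columns substitute independently per species at
    ``background_rate``.  Species ids are identical across subtypes, so the
    common-species filter keeps everything.  Deterministic under the seed.
    """
    spec = spec or MsaSpec()
    rng = np.random.default_rng(spec.seed)
    positions = _layout_positions(spec.layout)
    n_pos = len(positions)
    planted = set(spec.planted_labels)

    consensus = [_AA1[rng.integers(len(_AA1))] for _ in range(n_pos)]
    species = [spec.reference_species] + [
        f"species_{i:03d}" for i in range(1, spec.n_species)
    ]

    sets: dict[str, SequenceSet] = {}
    for subtype in spec.subtypes:
        records: list[tuple[str, str]] = []
        for sid in species:
            chars = []
            for (pos, label), base in zip(positions, consensus):
                if label in planted or sid == spec.reference_species:
                    chars.append(base)
                elif rng.random() < spec.background_rate:
                    alternatives = _AA1.replace(base, "")
                    chars.append(alternatives[rng.integers(len(alternatives))])
                else:
                    chars.append(base)
            records.append((sid, "".join(chars)))
        sets[subtype] = SequenceSet(subtype=subtype, records=records)

    entries = [
        GCLEntry(residue_number=pos, residue_name=_AA3[consensus[pos - 1]], label=label)
        for pos, label in positions
    ]
    table = GCLTable(subtype="reference", entries=entries)
    truth = {
        "seed": spec.seed,
        "planted_labels": sorted(str(l) for l in planted),
        "background_rate": spec.background_rate,
        "n_species": spec.n_species,
        "subtypes": list(spec.subtypes),
    }
    return MsaData(
        sets=sets,
        table=table,
        reference_lengths={s: n_pos for s in spec.subtypes},
        truth=truth,
    )
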