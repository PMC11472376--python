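"""Shared fixtures: random labeled structures and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from grkcc.labels import GCLEntry, GCLLabel, GCLTable, map_structure_to_gcl
from grkcc.structures import Atom, Residue, StructureModel


def make_random_labeled(
    rng: np.random.Generator,
    n_residues: int = 30,
    atoms_per_residue: int = 3,
    box: float = 20.0,
    unlabeled_every: int = 0,
    subtype: str = "GRK23",
):
    """A random-coordinate structure with a matching GCL table, fully mapped.

    Residues are split over a handful of SSE tokens so both residue- and
    element-level operations see several groups.  ``unlabeled_every > 0``
    leaves every k-th residue out of the table.
    """
    sse_tokens = [("RH", "H1"), ("RH", "H4H5"), ("KD", "S1"), ("KD", "HK"), ("KD", "HKHL")]
    residues, entries = [], []
    counters = {}
    names = ["ALA", "GLY", "SER", "LEU", "VAL", "ARG", "ASP", "PHE"]
    for i in range(1, n_residues + 1):
        atoms = []
        center = rng.uniform(0, box, size=3)
        for k in range(atoms_per_residue):
            pos = center + rng.normal(0, 1.0, size=3)
            atoms.append(
                Atom(name=f"C{k}" if k else "CA", element="C",
                     x=float(pos[0]), y=float(pos[1]), z=float(pos[2]))
            )
        residues.append(Residue(number=i, name=names[i % len(names)], atoms=atoms))
        if unlabeled_every and i % unlabeled_every == 0:
            continue
        dom, elem = sse_tokens[i % len(sse_tokens)]
        counters[(dom, elem)] = counters.get((dom, elem), 0) + 1
        entries.append(
            GCLEntry(i, names[i % len(names)], GCLLabel(dom, elem, counters[(dom, elem)]))
        )
    model = StructureModel(pdb_code="RAND", chain_id="A", resolution=2.0, residues=residues)
    table = GCLTable(subtype=subtype, entries=entries)
    return map_structure_to_gcl(model, table), table


def brute_force_contacts(ls, cutoff: float, min_gap: int):
    """Exhaustive double loop over labeled residue pairs and their heavy atoms."""
    out = set()
    labeled = [r for r in ls.residues if r.label is not None]
    for i, ri in enumerate(labeled):
        for rj in labeled[i + 1 :]:
            if abs(ri.chain_position - rj.chain_position) <= min_gap:
                continue
            ci = ls.structure.residues[ri.chain_position - 1].heavy_coords()
            cj = ls.structure.residues[rj.chain_position - 1].heavy_coords()
            dmin = min(
                float(np.linalg.norm(a - b)) for a in ci for b in cj
            ) if len(ci) and len(cj) else np.inf
            if dmin <= cutoff:
                pair = tuple(sorted((ri.label, rj.label), key=lambda l: l.sort_key))
                out.add(pair)
    return out


def brute_force_min_region_distance(ls, a, b):
    """Exhaustive min over all heavy-atom pairs between two labeled regions."""
    best = np.inf
    best_pair = None
    for ri in ls.residues:
        if ri.label is None or ri.label.sse != a:
            continue
        for rj in ls.residues:
            if rj.label is None or rj.label.sse != b:
                continue
            ci = ls.structure.residues[ri.chain_position - 1].heavy_coords()
            cj = ls.structure.residues[rj.chain_position - 1].heavy_coords()
            for x in ci:
                for y in cj:
                    d = float(np.linalg.norm(x - y))
                    if d < best - 1e-12:
                        best, best_pair = d, (ri.label, rj.label)
                    elif abs(d - best) <= 1e-12 and best_pair is not None:
                        cand = (ri.label.sort_key, rj.label.sort_key)
                        if cand < (best_pair[0].sort_key, best_pair[1].sort_key):
                            best_pair = (ri.label, rj.label)
    return best, best_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
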