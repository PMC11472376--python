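"""Shrake-Rupley SASA: closed forms, invariances, burial, and a biotite cross-check."""

import math

import numpy as np
import pytest

from grkcc.labels import GCLEntry, GCLLabel, GCLTable, map_structure_to_gcl
from grkcc.sasa import SasaPolicy, relative_sasa_by_state, shrake_rupley_sasa
from grkcc.structures import Atom, Residue, StructureModel


def _model(residues):
    return StructureModel("SASA", "A", 2.0, residues)


def _atom(name, element, x, y, z):
    return Atom(name, element, float(x), float(y), float(z))


def test_isolated_sphere_closed_form():
    # single S atom, vdW 1.8 + probe 1.4 -> full sphere 4*pi*3.2^2
    model = _model([Residue(1, "CYS", [_atom("SG", "S", 0, 0, 0)])])
    result = shrake_rupley_sasa(model, SasaPolicy())
    expected = 4 * math.pi * (1.8 + 1.4) ** 2
    assert result.total == pytest.approx(expected, rel=0.02)

    # custom radius 1.9 reproduces 4*pi*3.3^2 = 136.85
    policy = SasaPolicy(radius_table={"X": 1.9})
    model2 = _model([Residue(1, "GLY", [_atom("XX", "X", 0, 0, 0)])])
    assert shrake_rupley_sasa(model2, policy).total == pytest.approx(136.85, rel=0.02)


def test_distant_atoms_additive():
    model = _model(
        [
            Residue(1, "GLY", [_atom("CA", "C", 0, 0, 0)]),
            Residue(2, "GLY", [_atom("CA", "C", 50, 0, 0)]),
        ]
    )
    result = shrake_rupley_sasa(model)
    isolated = 4 * math.pi * (1.7 + 1.4) ** 2
    assert result.total == pytest.approx(2 * isolated, rel=1e-6)
    assert result.per_residue[0] == pytest.approx(isolated, rel=1e-6)


def _cage_atoms(radius=3.0, n=200):
    """A spherical shell of carbons tight enough to bury a central atom."""
    golden = math.pi * (3 - math.sqrt(5))
    atoms = []
    for k in range(n):
        z = 1 - (2 * k + 1) / n
        r = math.sqrt(max(1 - z * z, 0.0))
        theta = k * golden
        atoms.append(
            _atom(f"C{k}", "C", radius * r * math.cos(theta),
                  radius * r * math.sin(theta), radius * z)
        )
    return atoms


def test_caged_atom_is_buried():
    model = _model(
        [
            Residue(1, "GLY", [_atom("CA", "C", 0, 0, 0)]),
            Residue(2, "GLY", _cage_atoms()),
        ]
    )
    result = shrake_rupley_sasa(model)
    assert result.per_residue[0] == pytest.approx(0.0, abs=1e-9)


def test_burial_never_increases_sasa():
    target = Residue(1, "GLY", [_atom("CA", "C", 0, 0, 0)])
    prev = math.inf
    for n_occluders in (0, 2, 6, 12):
        occluders = [
            _atom(f"C{k}", "C", 3.0 * math.cos(2 * math.pi * k / 12),
                  3.0 * math.sin(2 * math.pi * k / 12), 0.0)
            for k in range(n_occluders)
        ]
        residues = [target] + ([Residue(2, "GLY", occluders)] if occluders else [])
        area = shrake_rupley_sasa(_model(residues)).per_residue[0]
        assert area <= prev + 1e-9
        prev = area


def test_rigid_motion_invariance(rng):
    residues = [
        Residue(i, "ALA", [_atom("CA", "C", *rng.uniform(0, 10, 3)),
                           _atom("CB", "C", *rng.uniform(0, 10, 3))])
        for i in range(1, 8)
    ]
    base = shrake_rupley_sasa(_model(residues)).total
    rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = []
    for res in residues:
        atoms = []
        for a in res.atoms:
            v = rot @ np.array([a.x, a.y, a.z]) + np.array([5.0, -3.0, 12.0])
            atoms.append(_atom(a.name, a.element, *v))
        moved.append(Residue(res.number, res.name, atoms))
    rotated = shrake_rupley_sasa(_model(moved)).total
    assert rotated == pytest.approx(base, rel=0.02)


def test_sphere_point_convergence(rng):
    residues = [
        Residue(i, "ALA", [_atom("CA", "C", *rng.uniform(0, 8, 3))])
        for i in range(1, 6)
    ]
    a960 = shrake_rupley_sasa(_model(residues), SasaPolicy(sphere_points=960)).total
    a3840 = shrake_rupley_sasa(_model(residues), SasaPolicy(sphere_points=3840)).total
    assert abs(a960 - a3840) / a3840 < 0.01


def test_unknown_element_is_error():
    model = _model([Residue(1, "GLY", [_atom("FE", "FE", 0, 0, 0)])])
    with pytest.raises(ValueError, match="FE"):
        shrake_rupley_sasa(model)


def test_agrees_with_biotite_on_random_structure(rng):
    """Independent oracle: biotite's own Shrake-Rupley on the same atoms."""
    biotite_struc = pytest.importorskip("biotite.structure")
    coords = rng.uniform(0, 12, size=(30, 3))
    residues = [
        Residue(i + 1, "GLY", [_atom("CA", "C", *coords[i])]) for i in range(30)
    ]
    ours = shrake_rupley_sasa(_model(residues), SasaPolicy(sphere_points=3840)).total

    arr = biotite_struc.AtomArray(30)
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, 31)
    arr.res_name[:] = "GLY"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    theirs = float(
        biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=1000, vdw_radii="Single"
        ).sum()
    )
    assert ours == pytest.approx(theirs, rel=0.03)


# ---------------------------------------------------------------------------
# rSASA by state


def _labeled_single(resname, target_xyz, occluded):
    """One labeled target residue, optionally ringed by occluding atoms."""
    atoms = [_atom("CA", "C", *target_xyz)]
    residues = [Residue(1, resname, atoms)]
    if occluded:
        residues.append(Residue(10, "GLY", _cage_atoms(radius=3.0)))
    entries = [GCLEntry(1, resname, GCLLabel("KD", "HB", 3))]
    model = _model(residues)
    return map_structure_to_gcl(model, GCLTable("GRK23", entries))


def test_exposed_residue_rsasa_near_reference():
    # an isolated glycine CA sphere exceeds the full-residue reference -> clamped
    ls = _labeled_single("GLY", (0, 0, 0), occluded=False)
    df = relative_sasa_by_state([ls], [ls], [GCLLabel("KD", "HB", 3)])
    assert df.loc[0, "mean_rsasa_closed"] > 0.9
    assert df.loc[0, "mean_rsasa_closed"] <= 1.2  # clamp honored


def test_planted_occlusion_gives_positive_difference():
    closed = [_labeled_single("GLY", (0, 0, 0), occluded=False)]
    open_ = [_labeled_single("GLY", (0, 0, 0), occluded=True)]
    df = relative_sasa_by_state(closed, open_, [GCLLabel("KD", "HB", 3)])
    assert df.loc[0, "difference"] > 0.5  # exposed when closed, hidden when open


def test_missing_reference_entry_is_error():
    ls = _labeled_single("UNK", (0, 0, 0), occluded=False)
    with pytest.raises(ValueError, match="UNK"):
        relative_sasa_by_state([ls], [ls], [GCLLabel("KD", "HB", 3)])


def test_position_missing_in_structure_is_skipped():
    ls = _labeled_single("GLY", (0, 0, 0), occluded=False)
    other = GCLLabel("RH", "H1", 1)
    df = relative_sasa_by_state([ls], [ls], [other])
    assert df.loc[0, "n_closed"] == 0 and math.isnan(df.loc[0, "mean_rsasa_closed"])
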