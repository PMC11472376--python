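"""The synthetic family/MSA generators and recovery of their planted truth."""

import dataclasses

import numpy as np
import pytest

from grkcc import contacts, states, structures, synthetic
from grkcc.conservation import conservation_scores, gcl_align
from grkcc.labels import GCLLabel, map_structure_to_gcl


@pytest.fixture(scope="module")
def family():
    return synthetic.generate_family(synthetic.FamilySpec(seed=11))


def _labeled_structures(family, tmp_path):
    paths = family.write(tmp_path)
    out = {}
    for sid in family.pdb_texts:
        models = structures.split_and_renumber_chains(
            structures.read_structures(paths[sid])
        )
        subfamily = sid.rsplit("_", 1)[0]
        for m in models:
            out[m.structure_id] = map_structure_to_gcl(m, family.tables[subfamily])
    return out


def test_determinism_byte_identical():
    a = synthetic.generate_family(synthetic.FamilySpec(seed=5))
    b = synthetic.generate_family(synthetic.FamilySpec(seed=5))
    assert a.pdb_texts == b.pdb_texts
    assert a.truth == b.truth
    noisy_a = synthetic.generate_family(
        synthetic.FamilySpec(seed=5, coordinate_noise=0.2)
    )
    noisy_b = synthetic.generate_family(
        synthetic.FamilySpec(seed=5, coordinate_noise=0.2)
    )
    assert noisy_a.pdb_texts == noisy_b.pdb_texts


def test_generated_files_accepted_by_io_and_labels(family, tmp_path):
    labeled = _labeled_structures(family, tmp_path)
    assert len(labeled) == 7 + 3 + 6 + 2
    for ls in labeled.values():
        assert ls.coverage == 1.0
        assert ls.structure.resolution == pytest.approx(2.5)


def test_state_recovery_matches_truth(family, tmp_path):
    labeled = _labeled_structures(family, tmp_path)
    for rec in family.truth["structures"]:
        call = states.lock_contact_pair(labeled[rec["id"]])
        assert call.state == rec["state"]
        assert call.distance == pytest.approx(rec["lock_distance"], abs=1e-6)
        la, _, lb, _ = call.closest_pair
        assert [str(la), str(lb)] == rec["closest_pair"]


def test_cc_truth_recovered_exactly(family, tmp_path):
    labeled = _labeled_structures(family, tmp_path)
    for subfamily in family.tables:
        closed = [ls for sid, ls in labeled.items()
                  if sid.startswith(subfamily) and "CLOSED" in sid]
        open_ = [ls for sid, ls in labeled.items()
                 if sid.startswith(subfamily) and "OPEN" in sid]
        table = contacts.conformational_change_scores(closed, open_)
        observed = {
            f"{p[0]}|{p[1]}": table.cc(p) for p in table.pairs
        }
        assert observed == family.truth["expected_cc"]


def test_lock_pair_residue_names_match_field_convention(family, tmp_path):
    # designated closest pair carries Val (RH.H4H5) and Arg (KD.HK.3)
    labeled = _labeled_structures(family, tmp_path)
    ls = next(iter(labeled.values()))
    call = states.lock_contact_pair(ls)
    _, name_a, lb, name_b = call.closest_pair
    assert name_a == "VAL" and name_b == "ARG" and str(lb) == "KD.HK.3"


@pytest.mark.parametrize(
    "change,match",
    [
        (synthetic.PlantedChange(
            (GCLLabel("RH", "H4H5", 1), GCLLabel("KD", "HKHL", 1)), "closed_only"),
         "lock region"),
        (synthetic.PlantedChange(
            (GCLLabel("RH", "H1", 1), GCLLabel("RH", "H1", 4)), "closed_only"),
         "sequence-gap"),
        (synthetic.PlantedChange(
            (GCLLabel("RH", "H1", 1), GCLLabel("PH", "H12", 1)), "closed_only"),
         "not in layout"),
    ],
)
def test_infeasible_geometry_rejected(change, match):
    spec = synthetic.FamilySpec(planted_changes=[change])
    with pytest.raises(ValueError, match=match):
        synthetic.generate_family(spec)


def test_duplicate_planted_residue_rejected():
    a = GCLLabel("RH", "H1", 1)
    spec = synthetic.FamilySpec(
        planted_changes=[
            synthetic.PlantedChange((a, GCLLabel("KD", "S1", 2)), "closed_only"),
            synthetic.PlantedChange((a, GCLLabel("KD", "HKHL", 3)), "open_only"),
        ]
    )
    with pytest.raises(ValueError, match="multiple planted pairs"):
        synthetic.generate_family(spec)


# ---------------------------------------------------------------------------
# alignments


def test_msa_determinism_and_rate_zero():
    a = synthetic.generate_msa(synthetic.MsaSpec(seed=3))
    b = synthetic.generate_msa(synthetic.MsaSpec(seed=3))
    assert {s: ss.records for s, ss in a.sets.items()} == {
        s: ss.records for s, ss in b.sets.items()
    }
    frozen = synthetic.generate_msa(synthetic.MsaSpec(seed=3, background_rate=0.0))
    ga = gcl_align(frozen.sets["GRK1"], frozen.table, "Homo_sapiens")
    profile = conservation_scores(ga)
    assert all(v == 11.0 for v in profile.defined().values())


def test_msa_planted_columns_invariant():
    data = synthetic.generate_msa(synthetic.MsaSpec(seed=4))
    ga = gcl_align(data.sets["GRK5"], data.table, "Homo_sapiens")
    profile = conservation_scores(ga)
    planted = set(data.truth["planted_labels"])
    for label, score in profile.defined().items():
        if str(label) in planted:
            assert score == 11.0


def test_msa_bad_rate_rejected():
    with pytest.raises(ValueError):
        synthetic.MsaSpec(background_rate=1.5)


def test_noisy_family_keeps_state_calls(tmp_path):
    # noise well below threshold margins: recovery stays 100%
    family = synthetic.generate_family(
        synthetic.FamilySpec(seed=21, coordinate_noise=0.05)
    )
    labeled = _labeled_structures(family, tmp_path)
    for rec in family.truth["structures"]:
        assert states.lock_contact_pair(labeled[rec["id"]]).state == rec["state"]


def test_cc_distribution_mass_near_zero_with_noise(tmp_path):
    """With coordinate noise, most residue pairs show little or no change."""
    family = synthetic.generate_family(
        synthetic.FamilySpec(seed=8, coordinate_noise=0.3)
    )
    labeled = _labeled_structures(family, tmp_path)
    closed = [ls for sid, ls in labeled.items()
              if sid.startswith("GRK23") and "CLOSED" in sid]
    open_ = [ls for sid, ls in labeled.items()
             if sid.startswith("GRK23") and "OPEN" in sid]
    table = contacts.conformational_change_scores(closed, open_)
    ccs = np.array([table.cc(p) for p in table.pairs])
    n_pairs_possible = 27 * 26 / 2
    # overwhelming majority of label pairs show |CC| < 1 (implicit zeros included)
    extreme = np.sum(np.abs(ccs) >= 1.0)
    assert extreme <= 4
    assert extreme / n_pairs_possible < 0.05
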