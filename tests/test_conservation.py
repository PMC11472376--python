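"""Sequence filtering, GCL-matched alignment, 0-11 conservation, group tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from grkcc.conservation import (
    AMAS_PROPERTIES,
    ConservationProfile,
    GclAlignment,
    SequenceSet,
    build_gcl_sequence_set,
    compare_position_groups,
    conservation_scores,
    gcl_align,
    residue_properties,
)
from grkcc.labels import GCLLabel, load_gcl_table


def _label(i):
    return GCLLabel("KD", "S1", i)


def _alignment(columns):
    """Build a GclAlignment from a list of column strings (one char per row)."""
    n_rows = len(columns[0])
    rows = [
        (f"sp{r}", "".join(col[r] for col in columns)) for r in range(n_rows)
    ]
    return GclAlignment(labels=[_label(i + 1) for i in range(len(columns))], rows=rows)


# ---------------------------------------------------------------------------
# filtering


def test_length_window_filter():
    raw = [
        SequenceSet("GRK1", [("A", "M" * 545), ("B", "M" * 529), ("C", "M" * 640)]),
        SequenceSet("GRK2", [("A", "M" * 590), ("B", "M" * 590), ("C", "M" * 590)]),
    ]
    filtered = build_gcl_sequence_set(raw, {"GRK1": 590, "GRK2": 590}, window=50)
    kept_1 = {sid for sid, _ in filtered[0].records}
    assert kept_1 == {"A", "C"}  # 545 and 640 within +/-50 of 590; 529 dropped


def test_common_species_intersection_and_count_identity():
    subtypes = [f"GRK{i}" for i in range(1, 8)]
    raw = []
    for i, s in enumerate(subtypes):
        species = ["A", "B", "C"] if i != 1 else ["A", "B"]
        raw.append(SequenceSet(s, [(sp, "M" * 100) for sp in species]))
    filtered = build_gcl_sequence_set(raw, {s: 100 for s in subtypes})
    for sset in filtered:
        assert sset.species == {"A", "B"}
    # 7 subtypes x k common species -> 7k sequences in total
    assert sum(len(s) for s in filtered) == 7 * 2


def test_no_common_species_is_error():
    raw = [
        SequenceSet("GRK1", [("A", "M" * 10)]),
        SequenceSet("GRK2", [("B", "M" * 10)]),
    ]
    with pytest.raises(ValueError, match="no common species"):
        build_gcl_sequence_set(raw, {"GRK1": 10, "GRK2": 10})


# ---------------------------------------------------------------------------
# GCL-matched alignment


TABLE = (
    "residue_number\tresidue_name\tgcl_label\n"
    "1\tMET\tKD.S1.1\n2\tALA\tKD.S1.2\n4\tGLY\tKD.S1.3\n"
)


def test_gcl_align_selects_labeled_reference_columns():
    table = load_gcl_table(TABLE, "reference")
    msa = SequenceSet(
        "GRK1",
        [("Homo_sapiens", "MAVG"), ("sp1", "MA-G"), ("sp2", "M-VG")],
    )
    ga = gcl_align(msa, table, "Homo_sapiens")
    assert [str(l) for l in ga.labels] == ["KD.S1.1", "KD.S1.2", "KD.S1.3"]
    rows = dict(ga.rows)
    assert rows["Homo_sapiens"] == "MAG"
    assert rows["sp1"] == "MAG"
    assert rows["sp2"] == "M-G"  # gap under a labeled column preserved


def test_gcl_align_skips_reference_gap_columns():
    table = load_gcl_table(TABLE, "reference")
    msa = SequenceSet(
        "GRK1", [("Homo_sapiens", "MA-VG"), ("sp1", "MAXVG")]
    )
    ga = gcl_align(msa, table, "Homo_sapiens")
    # reference residues are M(1) A(2) V(3) G(4); gap column dropped
    assert dict(ga.rows)["Homo_sapiens"] == "MAG"


def test_gcl_align_requires_reference():
    table = load_gcl_table(TABLE, "reference")
    msa = SequenceSet("GRK1", [("sp1", "MAVG")])
    with pytest.raises(ValueError, match="reference"):
        gcl_align(msa, table, "Homo_sapiens")


# ---------------------------------------------------------------------------
# conservation scores


def test_identity_column_scores_11():
    profile = conservation_scores(_alignment(["III", "AAA"]))
    assert profile.scores[_label(1)] == 11.0
    assert profile.scores[_label(2)] == 11.0


def test_all_gap_column_flagged_undefined():
    profile = conservation_scores(_alignment(["---", "AAA"]))
    assert profile.scores[_label(1)] is None
    assert _label(1) in profile.low_confidence
    assert profile.defined() == {_label(2): 11.0}


def test_ilv_column_matches_hand_intersection():
    # I, L, V: shared properties are exactly {hydrophobic, aliphatic}
    expected = residue_properties("I") & residue_properties("L") & residue_properties("V")
    assert expected == {"hydrophobic", "aliphatic"}
    profile = conservation_scores(_alignment(["ILV"]))
    assert profile.scores[_label(1)] == float(len(expected)) == 2.0


def test_identical_property_vectors_score_10():
    # I and L share the exact same AMAS property set but differ as residues
    assert residue_properties("I") == residue_properties("L")
    profile = conservation_scores(_alignment(["IL"]))
    assert profile.scores[_label(1)] == 10.0


def test_mostly_gapped_column_low_confidence():
    profile = conservation_scores(_alignment(["A---", "AAAA"]))
    assert _label(1) in profile.low_confidence
    assert profile.scores[_label(1)] == 11.0  # scored over the non-gap residues


def test_row_reorder_and_duplicate_invariance():
    cols = ["ILVA", "DDEE", "KKKK", "AGST"]
    base = conservation_scores(_alignment(cols))
    reordered = conservation_scores(
        GclAlignment(
            labels=[_label(i + 1) for i in range(len(cols))],
            rows=list(reversed(_alignment(cols).rows)),
        )
    )
    assert base.scores == reordered.scores
    ga = _alignment(cols)
    dup_rows = ga.rows + [("copy", ga.rows[0][1])]
    duplicated = conservation_scores(GclAlignment(labels=ga.labels, rows=dup_rows))
    assert base.scores == duplicated.scores


# ---------------------------------------------------------------------------
# group comparison


def _profile(selected_scores, background_scores):
    scores = {}
    for i, v in enumerate(selected_scores, start=1):
        scores[_label(i)] = float(v)
    for j, v in enumerate(background_scores, start=1):
        scores[GCLLabel("RH", "H1", j)] = float(v)
    selected = {_label(i) for i in range(1, len(selected_scores) + 1)}
    return ConservationProfile(scores=scores), selected


def test_identical_distributions_null():
    profile, selected = _profile([1, 2, 3, 4], [1, 2, 3, 4])
    comp = compare_position_groups(profile, selected)
    assert comp.u_statistic == pytest.approx(len(selected) * 4 / 2)
    assert comp.p_value == pytest.approx(1.0, abs=0.05)


def test_complete_separation_minimal_p():
    profile, selected = _profile([10, 10.5, 11, 10.2, 10.8], [1, 2, 3, 1.5, 2.5])
    comp = compare_position_groups(profile, selected)
    assert comp.u_statistic in (25.0, 0.0)
    # exact two-sided minimum for n1=n2=5: 2/C(10,5)
    assert comp.p_value == pytest.approx(2 / math.comb(10, 5), rel=1e-9)


def test_exact_p_matches_exhaustive_enumeration():
    x = [11.0, 9.0, 10.0, 8.0, 11.0]
    y = [3.0, 8.0, 5.0, 11.0, 2.0]
    profile, selected = _profile(x, y)
    comp = compare_position_groups(profile, selected)
    assert comp.method in ("exact", "enumeration")

    # independent oracle: enumerate all C(10,5) assignments of pooled ranks
    pooled = np.array(x + y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mean_u = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            hits += 1
    assert comp.p_value == pytest.approx(hits / total, rel=1e-12)
    assert comp.u_statistic == pytest.approx(u_obs)


def test_empty_or_degenerate_selection_errors():
    profile, _ = _profile([1, 2], [3, 4])
    with pytest.raises(ValueError):
        compare_position_groups(profile, set())
    with pytest.raises(ValueError):
        compare_position_groups(profile, set(profile.scores))  # no background left


def test_planted_high_conservation_recovered():
    rng = np.random.default_rng(7)
    background = rng.integers(0, 6, size=40).tolist()
    profile, selected = _profile([11] * 10, background)
    comp = compare_position_groups(profile, selected)
    assert comp.median_selected > comp.median_background
    assert comp.p_value < 1e-4
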