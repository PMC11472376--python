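"""GCL-matched alignments and physicochemical conservation scoring.

Sequences per subtype are filtered to a length window (default +/- 50
residues around the human reference) and restricted to species present in
every subtype, so that each subtype contributes an equal, comparable set.
Alignment columns are then re-keyed to GCL positions through the human
reference, and each column receives a conservation score on a 0-11 scale
built on the AMAS physicochemical residue classes:

* 11 — all non-gap residues identical;
* 10 — residues differ but share an identical full property set;
* otherwise — the number of physicochemical properties common to all
  non-gap residues in the column.

Group comparisons (e.g. transition-involved positions vs the rest) use a
two-sided Mann-Whitney U test, exact for small groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labels import GCLLabel, GCLTable

__all__ = [
    "AMAS_PROPERTIES",
    "SequenceSet",
    "GclAlignment",
    "ConservationProfile",
    "GroupComparison",
    "build_gcl_sequence_set",
    "gcl_align",
    "conservation_scores",
    "compare_position_groups",
    "read_fasta",
    "write_fasta",
]

GAP_CHARS = frozenset("-.")

# AMAS physicochemical residue classes (Taylor-style Venn groupings).
AMAS_PROPERTIES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFGHIKLMTVWY"),
    "polar": frozenset("CDEHKNQRSTWY"),
    "small": frozenset("ACDGNPSTV"),
    "proline": frozenset("P"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FHWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("DEHKR"),
}


def residue_properties(aa: str) -> frozenset[str]:
    aa = aa.upper()
    return frozenset(name for name, members in AMAS_PROPERTIES.items() if aa in members)


@dataclass
class SequenceSet:
    """Sequences of one subtype keyed by species id (amino acids + gaps)."""

    subtype: str
    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.subtype}: duplicate species ids")

    @property
    def species(self) -> set[str]:
        return {sid for sid, _ in self.records}

    def __len__(self) -> int:
        return len(self.records)


def _ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


def build_gcl_sequence_set(
    raw: Sequence[SequenceSet],
    reference_lengths: Mapping[str, int],
    window: int = 50,
) -> list[SequenceSet]:
    """Length-filter each subtype's sequences and keep only common species.

    A sequence survives if its ungapped length lies within
    ``[ref - window, ref + window]`` of the subtype's human reference
    length; afterwards only species present in *all* subtypes are kept, so
    every subtype ends with the same count.  Raises if no species is common
    to all subtypes.
    """
    filtered: list[SequenceSet] = []
    for sset in raw:
        ref = reference_lengths[sset.subtype]
        kept = [
            (sid, seq)
            for sid, seq in sset.records
            if abs(_ungapped_length(seq) - ref) <= window
        ]
        filtered.append(SequenceSet(sset.subtype, kept))
    common: set[str] | None = None
    for sset in filtered:
        common = sset.species if common is None else common & sset.species
    if not common:
        raise ValueError("no common species across subtypes after filtering")
    return [
        SequenceSet(
            sset.subtype,
            [(sid, seq) for sid, seq in sset.records if sid in common],
        )
        for sset in filtered
    ]


@dataclass
class GclAlignment:
    """Alignment whose columns are GCL positions of the reference sequence."""

    labels: list[GCLLabel]
    rows: list[tuple[str, str]]  # (species id, one character per label)

    def __post_init__(self) -> None:
        for sid, seq in self.rows:
            if len(seq) != len(self.labels):
                raise ValueError(f"row {sid}: length {len(seq)} != {len(self.labels)}")

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.rows)


def gcl_align(msa: SequenceSet, table: GCLTable, reference_id: str) -> GclAlignment:
    """Reduce an aligned set to the GCL-labeled columns of the reference.

    Columns where the reference has a gap, or whose reference residue
    number is absent from the table, are dropped; other sequences keep
    whatever the alignment placed there (residue or gap).
    """
    ref_seq = None
    for sid, seq in msa.records:
        if sid == reference_id:
            ref_seq = seq
            break
    if ref_seq is None:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    lengths = {len(seq) for _, seq in msa.records}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")

    lookup = table.by_residue_number()
    cols: list[int] = []
    labels: list[GCLLabel] = []
    res_no = 0
    for col, c in enumerate(ref_seq):
        if c in GAP_CHARS:
            continue
        res_no += 1
        entry = lookup.get(res_no)
        if entry is not None:
            cols.append(col)
            labels.append(entry.label)
    rows = [(sid, "".join(seq[c] for c in cols)) for sid, seq in msa.records]
    return GclAlignment(labels=labels, rows=rows)


def _column_score(column: str, max_gap_fraction: float) -> tuple[float | None, bool]:
    residues = [c.upper() for c in column if c not in GAP_CHARS]
    low_confidence = (len(column) - len(residues)) > max_gap_fraction * len(column)
    if not residues:
        return None, True
    if len(set(residues)) == 1:
        return 11.0, low_confidence
    prop_sets = [residue_properties(aa) for aa in set(residues)]
    if all(p == prop_sets[0] for p in prop_sets):
        return 10.0, low_confidence
    shared = frozenset.intersection(*prop_sets)
    return float(len(shared)), low_confidence


@dataclass
class ConservationProfile:
    """Per-GCL-position conservation scores on the 0-11 scale.

    ``scores[label] is None`` marks an undefined (all-gap) column;
    ``low_confidence`` flags columns with more than the configured gap
    fraction (default 50%).
    """

    scores: dict[GCLLabel, float | None]
    low_confidence: set[GCLLabel] = field(default_factory=set)

    def defined(self) -> dict[GCLLabel, float]:
        return {k: v for k, v in self.scores.items() if v is not None}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gcl_label": str(k),
                "score": ("" if v is None else v),
                "low_confidence": k in self.low_confidence,
            }
            for k, v in sorted(self.scores.items(), key=lambda kv: kv[0].sort_key)
        ]
        return pd.DataFrame(rows, columns=["gcl_label", "score", "low_confidence"])


def conservation_scores(
    gcl_msa: GclAlignment, max_gap_fraction: float = 0.5
) -> ConservationProfile:
    """Score every column of a GCL-matched alignment on the 0-11 scale."""
    if len(gcl_msa.rows) < 2:
        raise ValueError("need at least 2 sequences")
    scores: dict[GCLLabel, float | None] = {}
    low_conf: set[GCLLabel] = set()
    for i, label in enumerate(gcl_msa.labels):
        score, low = _column_score(gcl_msa.column(i), max_gap_fraction)
        scores[label] = score
        if low:
            low_conf.add(label)
    return ConservationProfile(scores=scores, low_confidence=low_conf)


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    median_selected: float
    median_background: float
    n_selected: int
    n_background: int
    method: str  # 'exact' | 'enumeration' | 'asymptotic'


def _enumeration_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Handles ties exactly; feasible only for small C(n1+n2, n1).
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mean_u = n1 * len(y) / 2
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


_ENUMERATION_LIMIT = 200_000


def compare_position_groups(
    profile: ConservationProfile, selected: Iterable[GCLLabel]
) -> GroupComparison:
    """Two-sided Mann-Whitney U: selected positions vs all other positions.

    Exact p-values for small groups (min group size <= 8): scipy's exact
    method when scores are tie-free, exhaustive enumeration of group
    assignments otherwise (when combinatorially feasible); the normal
    approximation with tie correction elsewhere.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("empty selected set")
    defined = profile.defined()
    x = np.array([v for k, v in defined.items() if k in selected], dtype=float)
    y = np.array([v for k, v in defined.items() if k not in selected], dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("selected must be a non-empty strict subset of scored positions")

    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = min(len(x), len(y)) <= 8
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u, p, method = float(res.statistic), float(res.pvalue), "exact"
    elif small and math.comb(len(x) + len(y), min(len(x), len(y))) <= _ENUMERATION_LIMIT:
        u, p = _enumeration_pvalue(x, y)
        method = "enumeration"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
    return GroupComparison(
        u_statistic=u,
        p_value=min(p, 1.0),
        median_selected=float(np.median(x)),
        median_background=float(np.median(y)),
        n_selected=len(x),
        n_background=len(y),
        method=method,
    )


def read_fasta(path, subtype: str) -> SequenceSet:
    """Read a FASTA file into a SequenceSet (record id = first header token)."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return SequenceSet(subtype=subtype, records=records)


def write_fasta(sset: SequenceSet, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sset.records
    ]
    SeqIO.write(recs, str(path), "fasta")
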