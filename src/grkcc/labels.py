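"""GRK Common Label (GCL) grammar, label tables, and structure-to-label mapping.

The GCL scheme assigns a three-part identifier ``DOMAIN.ELEMENT.INDEX`` to
topologically equivalent positions across the seven GRK subtypes, in the
spirit of generic residue-numbering schemes for GPCRs and G proteins.
``DOMAIN`` is one of ``RH`` (regulator-of-G-protein-signaling homology
domain), ``KD`` (kinase domain) or ``PH`` (pleckstrin homology domain,
GRK2/3 only); ``ELEMENT`` names a secondary-structure element or loop
(``H6``, ``HK``, ``H4H5``, ``S1S2``, ...); ``INDEX`` is the 1-based position
within that element.  ``RH.H6.3`` is the third position of RH-domain helix 6.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

__all__ = [
    "DOMAINS",
    "GCLLabel",
    "SSEKey",
    "GCLEntry",
    "GCLTable",
    "GCLParseError",
    "GCLValidationError",
    "LabeledResidue",
    "LabeledStructure",
    "parse_gcl_label",
    "load_gcl_table",
    "write_gcl_table",
    "map_structure_to_gcl",
]

DOMAINS = ("RH", "KD", "PH")


class GCLParseError(ValueError):
    """Raised when a string does not conform to the GCL label grammar."""


class GCLValidationError(ValueError):
    """Raised when a label table violates a uniqueness invariant."""


@dataclass(frozen=True)
class SSEKey:
    """A secondary-structure element identifier: a GCL label without the index."""

    domain: str
    element: str

    def __str__(self) -> str:
        return f"{self.domain}.{self.element}"

    @property
    def sort_key(self) -> tuple[str, str]:
        return (self.domain, self.element)

    @classmethod
    def parse(cls, text: str) -> "SSEKey":
        parts = text.split(".")
        if len(parts) != 2:
            raise GCLParseError(f"SSE key {text!r}: expected DOMAIN.ELEMENT")
        domain, element = parts
        if domain not in DOMAINS:
            raise GCLParseError(f"SSE key {text!r}: unknown domain {domain!r}")
        if not element:
            raise GCLParseError(f"SSE key {text!r}: empty element token")
        return cls(domain, element)


@dataclass(frozen=True)
class GCLLabel:
    """A three-part GCL position identifier (domain, element, 1-based index)."""

    domain: str
    element: str
    index: int

    def __str__(self) -> str:
        return f"{self.domain}.{self.element}.{self.index}"

    @property
    def sse(self) -> SSEKey:
        return SSEKey(self.domain, self.element)

    @property
    def sort_key(self) -> tuple[str, str, int]:
        return (self.domain, self.element, self.index)


def parse_gcl_label(text: str) -> GCLLabel:
    """Parse a canonical ``DOMAIN.ELEMENT.INDEX`` string into a :class:`GCLLabel`.

    The element vocabulary is open (any non-empty alphanumeric token); only
    the grammar is validated.  Raises :class:`GCLParseError` naming the
    offending part on malformed input.
    """
    if not text:
        raise GCLParseError("empty label string")
    parts = text.split(".")
    if len(parts) != 3:
        raise GCLParseError(
            f"label {text!r}: expected exactly two dots (DOMAIN.ELEMENT.INDEX)"
        )
    domain, element, index_str = parts
    if domain not in DOMAINS:
        raise GCLParseError(
            f"label {text!r}: unknown domain {domain!r} (expected one of {DOMAINS})"
        )
    if not element or not element.isalnum():
        raise GCLParseError(f"label {text!r}: bad element token {element!r}")
    try:
        index = int(index_str)
    except ValueError:
        raise GCLParseError(f"label {text!r}: non-integer index {index_str!r}") from None
    if index < 1:
        raise GCLParseError(f"label {text!r}: index must be >= 1, got {index}")
    return GCLLabel(domain, element, index)


@dataclass(frozen=True)
class GCLEntry:
    residue_number: int
    residue_name: str
    label: GCLLabel


@dataclass
class GCLTable:
    """Per-subtype mapping from author residue numbers to GCL labels.

    Labels and residue numbers are each unique within the table; row order
    is preserved.
    """

    subtype: str
    entries: list[GCLEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen_labels: dict[GCLLabel, int] = {}
        seen_numbers: dict[int, int] = {}
        dup_labels, dup_numbers = [], []
        for entry in self.entries:
            if entry.label in seen_labels:
                dup_labels.append(str(entry.label))
            if entry.residue_number in seen_numbers:
                dup_numbers.append(entry.residue_number)
            seen_labels[entry.label] = seen_labels.get(entry.label, 0) + 1
            seen_numbers[entry.residue_number] = (
                seen_numbers.get(entry.residue_number, 0) + 1
            )
        if dup_labels or dup_numbers:
            raise GCLValidationError(
                f"table for {self.subtype}: duplicate labels {dup_labels}, "
                f"duplicate residue numbers {dup_numbers}"
            )

    def by_residue_number(self) -> dict[int, GCLEntry]:
        return {e.residue_number: e for e in self.entries}

    def by_label(self) -> dict[GCLLabel, GCLEntry]:
        return {e.label: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


_TABLE_COLUMNS = ("residue_number", "residue_name", "gcl_label")


def load_gcl_table(source: TextIO | str, subtype: str) -> GCLTable:
    """Read a GCL table from TSV with header ``residue_number residue_name gcl_label``.

    Raises :class:`GCLParseError` (with the 1-based data row number) on an
    unparseable label, and :class:`GCLValidationError` on duplicates.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.DictReader(source, delimiter="\t")
    if reader.fieldnames is None or [c for c in _TABLE_COLUMNS if c not in reader.fieldnames]:
        raise GCLParseError(
            f"GCL table must have columns {_TABLE_COLUMNS}, got {reader.fieldnames}"
        )
    entries = []
    for row_no, row in enumerate(reader, start=1):
        try:
            label = parse_gcl_label(row["gcl_label"])
        except GCLParseError as exc:
            raise GCLParseError(f"row {row_no}: {exc}") from None
        entries.append(
            GCLEntry(
                residue_number=int(row["residue_number"]),
                residue_name=row["residue_name"].strip().upper(),
                label=label,
            )
        )
    return GCLTable(subtype=subtype, entries=entries)


def write_gcl_table(table: GCLTable, dest: TextIO) -> None:
    """Write a GCL table as canonical TSV (inverse of :func:`load_gcl_table`)."""
    dest.write("\t".join(_TABLE_COLUMNS) + "\n")
    for e in table.entries:
        dest.write(f"{e.residue_number}\t{e.residue_name}\t{e.label}\n")


@dataclass
class LabeledResidue:
    """A structure residue joined with its GCL label (``label is None`` if unlabeled)."""

    chain_position: int  # 1-based position in the renumbered chain
    residue_number: int  # author numbering, as keyed by the GCL table
    residue_name: str
    label: GCLLabel | None
    name_mismatch: bool = False


@dataclass
class LabeledStructure:
    """A single-chain structure with its residue -> GCL mapping.

    ``coverage`` is the fraction of table labels found in the structure.
    Unlabeled residues are retained (they still occupy chain positions for
    sequence-gap computations) but are excluded from all scoring.
    """

    structure: "StructureModel"  # noqa: F821 - forward ref to structures module
    subtype: str
    residues: list[LabeledResidue]
    coverage: float

    @property
    def structure_id(self) -> str:
        return self.structure.structure_id

    def labeled(self) -> list[LabeledResidue]:
        return [r for r in self.residues if r.label is not None]

    def label_map(self) -> dict[GCLLabel, LabeledResidue]:
        return {r.label: r for r in self.residues if r.label is not None}

    def sse_members(self, key: SSEKey) -> list[LabeledResidue]:
        return [
            r
            for r in self.residues
            if r.label is not None and r.label.sse == key
        ]


def map_structure_to_gcl(structure: "StructureModel", table: GCLTable) -> LabeledStructure:  # noqa: F821
    """Join a single-chain structure with a GCL table by author residue number.

    Residue-name mismatches between table and structure are tolerated
    (engineered mutants occur in deposited entries) and flagged per residue.
    Raises ``ValueError`` if no residue number overlaps the table.
    """
    lookup = table.by_residue_number()
    labeled: list[LabeledResidue] = []
    n_mapped = 0
    for pos, res in enumerate(structure.residues, start=1):
        entry = lookup.get(res.author_number)
        if entry is None:
            labeled.append(
                LabeledResidue(pos, res.author_number, res.name, None)
            )
        else:
            n_mapped += 1
            labeled.append(
                LabeledResidue(
                    pos,
                    res.author_number,
                    res.name,
                    entry.label,
                    name_mismatch=(entry.residue_name != res.name),
                )
            )
    if n_mapped == 0:
        raise ValueError(
            f"{structure.structure_id}: no overlap between table and structure numbering"
        )
    coverage = n_mapped / len(table) if len(table) else 0.0
    return LabeledStructure(
        structure=structure,
        subtype=table.subtype,
        residues=labeled,
        coverage=coverage,
    )
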