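# Methods

This note documents the models, conventions and numerical choices behind
`grkcc`, and what the synthetic-data tests do and do not demonstrate.

## Common labels (GCL)

A GCL label is `DOMAIN.ELEMENT.INDEX` with `DOMAIN ∈ {RH, KD, PH}`, an
open alphanumeric element vocabulary (helices `H…`, strands `S…`, loops as
concatenations such as `H4H5` or `HKHL`), and a 1-based index within the
element. The grammar is validated strictly (two dots, known domain,
positive index) but the element vocabulary is deliberately permissive:
label tables are *inputs*, produced upstream by structure superposition,
and the pipeline should not reject a table over an unknown loop name.
Tables are TSV (`residue_number  residue_name  gcl_label`), one per
subtype, keyed to the *author* residue numbering of the deposited entry.
Residue-name mismatches between table and structure are flagged per
residue but tolerated, because deposited entries frequently carry
engineered point mutations.

## Structure preparation

Chains are read with gemmi, split into independent structures, and
renumbered sequentially from 1; author numbering is retained so label
tables still apply, while sequence gaps for the contact definition use the
renumbered positions. Filters: resolution strictly above 4.00 Å (exactly
4.00 is kept), unknown resolution (dropped by default; the analyzed
entries are crystallographic/cryo-EM with stated resolutions), and label
coverage < 50% of the table ("short fragments" — coverage is the property
downstream scoring actually needs, so it operationalizes the fragment
filter; the threshold is configurable). Alternate locations keep the
highest-occupancy conformer (ties prefer altloc `A`). Waters and ligands
are excluded; modified amino acids are kept when they carry a CA atom.
Hydrogens and deuteriums are excluded from every distance computation.

## State classification

The lock distance is the minimum over all heavy-atom pairs between the
labeled residues of `RH.H4H5` and `KD.HK` (a CA-only mode would be less
consistent with the heavy-atom contact definition used everywhere else).
Closed means distance < 3.3 Å, open > 5.0 Å; boundary equality is
intermediate because the criteria are strictly "under"/"over".
Intermediates retain their state call but never enter group averages.
Exact distance ties report the lexicographically smallest label pair, so
output is deterministic.

## Contact and change scores

A residue pair is in contact iff sequence gap > 5 (strict: gap 6 is the
first long-range separation) and minimal heavy-atom distance ≤ cutoff
(inclusive). **The cutoff, 4.5 Å, is this package's explicit choice of a
standard heavy-atom contact threshold**; it is a `ContactPolicy` field and
echoed into every output manifest so that sensitivity analyses (4.0–5.0 Å
is the reasonable range) are one config edit away. Only labeled residues
participate: positions without a common label are not comparable across
structures, though they still occupy chain positions for the gap rule.

ACS is the per-group contact frequency in [0, 1]; pairs never in contact
are implicit zeros. SSE-level scores count contacting residue pairs per
element pair (intra-element pairs included when they pass the gap rule),
so the element-pair scores sum exactly to the residue-level contact count.
CC = ACS_closed − ACS_open at either level; CC = 0 pairs are retained and
flagged "no change".

PH-domain positions (GRK2/3 only) flow through the same machinery; because
networks are built from pairs present in *both* subfamily tables, PH pairs
can never enter a cross-subfamily common-tendency network, which keeps the
GRK2/3-specific domain out of pooled comparisons by construction.

## Change networks

A pair shows a common tendency when its CC is nonzero with the same sign
in both subfamilies; opposite signs indicate subfamily bias and are
excluded, and zero has no sign. Edge weight is the summed CC. At residue
level, edges require |sum| strictly > 1 (with same-sign filtering, the
readings |a + b| and |a| + |b| coincide, so the ambiguity is moot); at SSE
level no magnitude threshold applies. Hubs are identified by node degree —
no stronger centrality claim is made. GraphML and JSON exports are
lossless and deterministically ordered; TSV is a flat edge table.

## Conservation

Sequences per subtype are filtered to ungapped length within ±50 of the
human reference and to species present in all seven subtypes, so each
subtype contributes the same species count (k species ⇒ 7k sequences
total). Alignment columns are re-keyed to GCL positions through the human
reference; columns where the reference is unlabeled or gapped are dropped.

The 0–11 column score is built on the AMAS physicochemical classes
(hydrophobic, polar, small, proline, tiny, aliphatic, aromatic, positive,
negative, charged): 11 for an identical column, 10 when all residues share
an identical full property vector, otherwise the size of the intersection
of the residues' property sets. This is a deliberate simplification of the
Livingstone–Barton convention (which also counts conserved *absence* of a
property); it preserves the ordering that matters here — identity >
conservative substitution > divergent column — and is fully specified by
the class table shipped in `conservation.AMAS_PROPERTIES`. Gaps are
excluded from the shared set; all-gap columns are undefined and flagged;
columns over 50% gaps are flagged low-confidence (configurable).

Group comparison uses a two-sided Mann–Whitney U. For small groups
(min n ≤ 8) the p-value is exact: scipy's exact method when the pooled
scores are tie-free, otherwise exhaustive enumeration of all group
assignments when C(n₁+n₂, min) ≤ 2×10⁵ (integer conservation scores tie
heavily, and enumeration is the only tie-exact method available at these
sizes). Larger problems use the normal approximation with tie correction.

## SASA

Shrake–Rupley with a deterministic golden-spiral lattice (default 960
points), probe 1.4 Å (water), and standard van der Waals radii (C 1.70,
N 1.55, O 1.52, S 1.80 Å, …). An atom's area is its accessible point
fraction times 4π(r_vdW + probe)²; residues sum their heavy atoms.
rSASA divides by the Tien et al. theoretical maximum accessible area per
residue type and clamps to [0, 1.2] (observed areas can slightly exceed
tabulated maxima). Unknown elements and residue types raise rather than
guess. Sampling error at 960 points is well under 2% on convex fixtures;
rigid-body motion changes areas only through lattice orientation, again
under 2%.

## Synthetic data

The generator produces the *study conditions* the pipeline is evaluated
under: two subfamilies sized 7 closed + 3 open (GRK2/3) and 6 closed +
2 open (GRK4/5/6), lock distances 2.8 Å (closed) / 6.5 Å (open), and three
planted contact changes (closed-only, open-only, state-independent).
Geometry is deliberately minimal: each residue is a rigid N/CA/C/O stack
at fixed vertical offsets, scaffold residues sit 8 Å apart (no accidental
contacts), lock regions are parallel rows whose designated pair (Val in
`RH.H4H5`, Arg at `KD.HK.3`, matching the subfamily's conserved lock
chemistry) realizes the requested minimal distance exactly, and planted
pairs meet at isolated sites 3.5 Å apart (contact) or 20 Å apart (no
contact). Optional Gaussian coordinate noise perturbs every atom.

Consequently, zero-noise recovery is *exact* — states 100%, CC ∈ {−1, 0, 1}
on planted/unplanted pairs, network equal to the planted set — and that is
what the acceptance checks assert. What passing these tests shows is that
the scoring machinery is correct, deterministic and self-consistent; what
they cannot show is robustness to the messiness of real crystal structures
(missing side chains, alternate conformers, genuinely intermediate
geometries, label tables with partial coverage), which only the real
deposited ensemble can probe. Alignments are generated gap-free with
planted invariant columns against an i.i.d. substitution background
(default rate 0.5 per sequence and column, 37 species × 7 subtypes); real
alignments have phylogenetic correlation the generator does not emulate,
so the planted-detection p-values demonstrate the statistic, not a power
claim about vertebrate GRK sequences.

Problem sizes throughout the tests (≤ 50-residue structures, ≤ 20-member
groups, 27-position alignments) are chosen so the exhaustive brute-force
oracles stay trivially cheap while still exercising every code path.

## Known limitations

* The heavy-atom cutoff has no single canonical value; conclusions near
  the 4.5 Å default should be checked across 4.0–5.0 Å.
* Insertion codes are passed through but not used for ordering.
* The conservation score simplifies the Jalview/AMAS convention (see
  above); absolute scores are not interchangeable with Jalview output,
  though rankings of clearly conserved vs divergent columns agree.
* mmCIF input, assembly generation and figure rendering are out of scope.
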