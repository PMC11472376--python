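"""End-to-end orchestration: structures -> labels -> states -> scores -> networks.

A single declarative :class:`RunConfig` (YAML-serializable) drives the full
analysis and produces a reproducible report bundle: TSV tables for every
intermediate quantity, GraphML/JSON networks, and a JSON manifest echoing
every policy value and seed.  Runs are deterministic: identical config and
inputs give identical bundle content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation as cons
from . import contacts, networks, sasa, states, structures, synthetic
from .labels import (
    GCLTable,
    SSEKey,
    load_gcl_table,
    map_structure_to_gcl,
    parse_gcl_label,
)

__all__ = ["RunConfig", "RunReport", "run_full_pipeline", "load_config", "save_config"]

log = logging.getLogger("grkcc.pipeline")


@dataclass
class StructureInput:
    path: str
    subfamily: str


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    output_dir: str = "grkcc_run"
    seed: int = 0
    # synthetic mode (default) or explicit input files
    use_synthetic: bool = True
    family: synthetic.FamilySpec = field(default_factory=synthetic.FamilySpec)
    msa: synthetic.MsaSpec | None = field(default_factory=synthetic.MsaSpec)
    structure_inputs: list[StructureInput] = field(default_factory=list)
    gcl_table_paths: dict[str, str] = field(default_factory=dict)  # subfamily -> TSV
    msa_paths: dict[str, str] = field(default_factory=dict)        # subtype -> FASTA
    msa_table_path: str | None = None
    msa_reference: str = "Homo_sapiens"
    # policies
    filter_policy: structures.FilterPolicy = field(default_factory=structures.FilterPolicy)
    thresholds: states.StateThresholds = field(default_factory=states.StateThresholds)
    contact_policy: contacts.ContactPolicy = field(default_factory=contacts.ContactPolicy)
    network_policy: networks.NetworkPolicy = field(default_factory=networks.NetworkPolicy)
    sasa_policy: sasa.SasaPolicy = field(default_factory=sasa.SasaPolicy)
    rsasa_positions: list[str] = field(default_factory=list)  # canonical GCL labels

    def __post_init__(self) -> None:
        if self.use_synthetic:
            self.family = dataclasses.replace(self.family, seed=self.seed)
            if self.msa is not None:
                self.msa = dataclasses.replace(self.msa, seed=self.seed)


def _policies_dict(config: RunConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, SSEKey):
            return str(obj)
        return obj

    return {
        "seed": config.seed,
        "filter_policy": plain(config.filter_policy),
        "thresholds": {
            "closed_max": config.thresholds.closed_max,
            "open_min": config.thresholds.open_min,
            "region_a": str(config.thresholds.region_a),
            "region_b": str(config.thresholds.region_b),
        },
        "contact_policy": plain(config.contact_policy),
        "network_policy": plain(config.network_policy),
        "sasa_policy": {
            "probe_radius": config.sasa_policy.probe_radius,
            "sphere_points": config.sasa_policy.sphere_points,
        },
    }


@dataclass
class RunReport:
    outdir: Path
    manifest: dict
    state_calls: list[states.StateCall]
    score_tables: dict  # (subfamily, level) -> ScoreTable
    residue_network: networks.ChangeNetwork | None
    sse_network: networks.ChangeNetwork | None
    conservation_comparison: cons.GroupComparison | None


def _gather_inputs(config: RunConfig, outdir: Path):
    """Resolve structures and tables, generating synthetic inputs if requested."""
    if config.use_synthetic:
        family = synthetic.generate_family(config.family)
        input_dir = outdir / "inputs"
        family.write(input_dir)
        structure_inputs = []
        for subfamily in family.tables:
            for sid in family.pdb_texts:
                if sid.startswith(subfamily + "_"):
                    structure_inputs.append(
                        StructureInput(str(input_dir / f"{sid}.pdb"), subfamily)
                    )
        tables = family.tables
        return structure_inputs, tables, family.truth
    tables = {}
    for subfamily, path in config.gcl_table_paths.items():
        with open(path) as fh:
            tables[subfamily] = load_gcl_table(fh, subfamily)
    return list(config.structure_inputs), tables, None


def _run_conservation(config: RunConfig, outdir: Path, selected_labels):
    if config.use_synthetic:
        if config.msa is None:
            return None, None
        msa_data = synthetic.generate_msa(config.msa)
        msa_data.write(outdir / "inputs")
        sets = list(msa_data.sets.values())
        table = msa_data.table
        ref_lengths = msa_data.reference_lengths
        reference = config.msa.reference_species
    elif config.msa_paths and config.msa_table_path:
        sets = [
            cons.read_fasta(path, subtype) for subtype, path in config.msa_paths.items()
        ]
        with open(config.msa_table_path) as fh:
            table = load_gcl_table(fh, "reference")
        ref_lengths = {}
        for sset in sets:
            for sid, seq in sset.records:
                if sid == config.msa_reference:
                    ref_lengths[sset.subtype] = sum(
                        1 for c in seq if c not in cons.GAP_CHARS
                    )
        reference = config.msa_reference
    else:
        return None, None

    filtered = cons.build_gcl_sequence_set(sets, ref_lengths)
    aligned = [cons.gcl_align(sset, table, reference) for sset in filtered]
    # pooled alignment across subtypes: same label columns, stacked rows
    labels = aligned[0].labels
    pooled_rows = []
    for sset, ga in zip(filtered, aligned):
        pooled_rows.extend(
            (f"{sset.subtype}:{sid}", seq) for sid, seq in ga.rows
        )
    pooled = cons.GclAlignment(labels=labels, rows=pooled_rows)
    profile = cons.conservation_scores(pooled)
    profile.to_dataframe().to_csv(outdir / "conservation.tsv", sep="\t", index=False)

    comparison = None
    selected = {l for l in selected_labels if l in profile.scores}
    if selected and len(selected) < len(profile.defined()):
        comparison = cons.compare_position_groups(profile, selected)
    return profile, comparison


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Raises ``ValueError`` ("insufficient structures for closed/open
    comparison") if any analyzed subfamily lacks a closed or open group
    after classification.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    structure_inputs, tables, truth = _gather_inputs(config, outdir)
    log.info("inputs: %d structure files, %d tables", len(structure_inputs), len(tables))

    # read -> split/renumber -> label -> filter
    labeled_by_subfamily: dict[str, list] = {s: [] for s in tables}
    inventory_rows = []
    for sinput in structure_inputs:
        models = structures.read_structures(sinput.path)
        models = structures.split_and_renumber_chains(models)
        table = tables[sinput.subfamily]
        labeled = [map_structure_to_gcl(m, table) for m in models]
        kept, dropped = structures.filter_structures(
            models, [ls.coverage for ls in labeled], config.filter_policy
        )
        kept_ids = {m.structure_id for m in kept}
        for ls in labeled:
            status = "kept" if ls.structure_id in kept_ids else "dropped"
            reason = ""
            for d in dropped:
                if d.model.structure_id == ls.structure_id:
                    reason = d.reason
            inventory_rows.append(
                {
                    "structure_id": ls.structure_id,
                    "subfamily": sinput.subfamily,
                    "resolution": ls.structure.resolution,
                    "coverage": round(ls.coverage, 4),
                    "status": status,
                    "reason": reason,
                }
            )
            if status == "kept":
                labeled_by_subfamily[sinput.subfamily].append(ls)
    pd.DataFrame(inventory_rows).sort_values("structure_id").to_csv(
        outdir / "inventory.tsv", sep="\t", index=False
    )

    # state classification
    state_calls = []
    groups: dict[str, dict[str, list]] = {
        s: {"closed": [], "open": [], "intermediate": []} for s in tables
    }
    state_rows = []
    for subfamily, group in labeled_by_subfamily.items():
        for ls in group:
            call = states.lock_contact_pair(ls, config.thresholds)
            state_calls.append(call)
            groups[subfamily][call.state].append(ls)
            la, na, lb, nb = call.closest_pair
            state_rows.append(
                {
                    "structure_id": call.structure_id,
                    "subfamily": subfamily,
                    "distance_A": round(call.distance, 3),
                    "state": call.state,
                    "label_a": str(la),
                    "resname_a": na,
                    "label_b": str(lb),
                    "resname_b": nb,
                }
            )
    pd.DataFrame(state_rows).sort_values("structure_id").to_csv(
        outdir / "states.tsv", sep="\t", index=False
    )

    # per-subfamily CC tables at both levels
    score_tables = {}
    for subfamily, by_state in groups.items():
        for state_name in ("closed", "open"):
            if not by_state[state_name]:
                raise ValueError(
                    "insufficient structures for closed/open comparison: "
                    f"subfamily {subfamily} has no {state_name} group"
                )
        for level in ("residue", "sse"):
            table = contacts.conformational_change_scores(
                by_state["closed"], by_state["open"], config.contact_policy, level
            )
            score_tables[(subfamily, level)] = table
            table.to_dataframe().to_csv(
                outdir / f"scores_{subfamily}_{level}.tsv", sep="\t", index=False
            )

    # common-tendency networks across the (first two) subfamilies
    residue_net = sse_net = None
    subfamilies = list(tables)
    if len(subfamilies) >= 2:
        a, b = subfamilies[0], subfamilies[1]
        for level, name in (("residue", "residue_network"), ("sse", "sse_network")):
            common = networks.common_tendency_pairs(
                score_tables[(a, level)], score_tables[(b, level)]
            )
            net = networks.build_change_network(common, config.network_policy, level)
            networks.export_graph(net, outdir / f"{name}.graphml", "graphml")
            networks.export_graph(net, outdir / f"{name}.json", "json-edges")
            networks.export_graph(net, outdir / f"{name}.tsv", "tsv")
            if level == "residue":
                residue_net = net
            else:
                sse_net = net

    # conservation: transition-involved positions (residue-network nodes)
    selected_labels = set()
    if residue_net is not None:
        selected_labels = {parse_gcl_label(n) for n in residue_net.graph.nodes}
    profile, comparison = _run_conservation(config, outdir, selected_labels)

    # optional rSASA comparison on caller-specified positions
    if config.rsasa_positions and len(subfamilies) >= 1:
        positions = [parse_gcl_label(s) for s in config.rsasa_positions]
        closed_all = [ls for s in subfamilies for ls in groups[s]["closed"]]
        open_all = [ls for s in subfamilies for ls in groups[s]["open"]]
        sasa.relative_sasa_by_state(
            closed_all, open_all, positions, config.sasa_policy
        ).to_csv(outdir / "rsasa.tsv", sep="\t", index=False)

    manifest = {
        "policies": _policies_dict(config),
        "counts": {
            "structures_in": len(inventory_rows),
            "structures_kept": sum(1 for r in inventory_rows if r["status"] == "kept"),
            "states": {
                s: {k: len(v) for k, v in by_state.items()}
                for s, by_state in groups.items()
            },
            "residue_network_edges": (
                len(residue_net.edges) if residue_net is not None else None
            ),
            "sse_network_edges": len(sse_net.edges) if sse_net is not None else None,
        },
        "conservation": (
            None
            if comparison is None
            else {
                "u_statistic": comparison.u_statistic,
                "p_value": comparison.p_value,
                "median_selected": comparison.median_selected,
                "median_background": comparison.median_background,
                "n_selected": comparison.n_selected,
                "n_background": comparison.n_background,
                "method": comparison.method,
            }
        ),
        "truth_available": truth is not None,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return RunReport(
        outdir=outdir,
        manifest=manifest,
        state_calls=state_calls,
        score_tables=score_tables,
        residue_network=residue_net,
        sse_network=sse_net,
        conservation_comparison=comparison,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization


def _config_to_dict(config: RunConfig) -> dict:
    d = {
        "output_dir": config.output_dir,
        "seed": config.seed,
        "use_synthetic": config.use_synthetic,
        "policies": _policies_dict(config),
        "structure_inputs": [
            {"path": s.path, "subfamily": s.subfamily} for s in config.structure_inputs
        ],
        "gcl_table_paths": dict(config.gcl_table_paths),
        "msa_paths": dict(config.msa_paths),
        "msa_table_path": config.msa_table_path,
        "msa_reference": config.msa_reference,
        "rsasa_positions": list(config.rsasa_positions),
    }
    return d


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    policies = d.get("policies", {})
    thresholds = policies.get("thresholds", {})
    config = RunConfig(
        output_dir=d.get("output_dir", "grkcc_run"),
        seed=d.get("seed", 0),
        use_synthetic=d.get("use_synthetic", True),
        structure_inputs=[
            StructureInput(**s) for s in d.get("structure_inputs", [])
        ],
        gcl_table_paths=d.get("gcl_table_paths", {}),
        msa_paths=d.get("msa_paths", {}),
        msa_table_path=d.get("msa_table_path"),
        msa_reference=d.get("msa_reference", "Homo_sapiens"),
        filter_policy=structures.FilterPolicy(**policies.get("filter_policy", {})),
        thresholds=states.StateThresholds(
            closed_max=thresholds.get("closed_max", 3.3),
            open_min=thresholds.get("open_min", 5.0),
            region_a=SSEKey.parse(thresholds.get("region_a", "RH.H4H5")),
            region_b=SSEKey.parse(thresholds.get("region_b", "KD.HK")),
        ),
        contact_policy=contacts.ContactPolicy(**policies.get("contact_policy", {})),
        network_policy=networks.NetworkPolicy(**policies.get("network_policy", {})),
        sasa_policy=sasa.SasaPolicy(**policies.get("sasa_policy", {})),
        rsasa_positions=d.get("rsasa_positions", []),
    )
    return config
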