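"""End-to-end orchestration: secretome catalog -> differential readouts ->
cytometry summary -> interaction network -> mediator candidates.

Stages run in the order of the study design (retrieve conditioned-medium
interactions, attach differential measured factors, select candidates); every
stage logs its counts and the report carries SHA-256 checksums of all inputs
and outputs so runs are diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cytometry, expression, interactome, proteomics, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults follow the study design:
    1% FDR, two-peptide rule, |log2fc| >= 1 differential calls, hubs at more
    than five measured factors."""

    psms: str
    id_mapping: str
    biogrid: str
    cytokines: str
    ct: str
    events: str
    outdir: str
    fdr_level: float = 0.01
    min_unique_peptides: int = 2
    log2fc_threshold: float = 1.0
    p_threshold: float | None = None
    min_measured_degree: int = 6
    taxon: int | None = 9606
    system_type: str | None = None
    housekeeping_gene: str = synthetic.HOUSEKEEPING_GENE
    treated_condition: str = "ipsc_cm"
    control_condition: str = "control"
    gate_thresholds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be positive")
        if self.min_measured_degree < 1:
            raise ValueError("min_measured_degree must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "provenance": {"inputs": {}, "outputs": {}}}
    for name in ("psms", "id_mapping", "biogrid", "cytokines", "ct", "events"):
        report["provenance"]["inputs"][name] = _sha256(Path(getattr(config, name)))

    # -- stage 1: proteomics ------------------------------------------------
    psms = proteomics.read_psm_table(config.psms)
    catalogs = {
        medium: proteomics.build_catalog(
            psms,
            fdr_level=config.fdr_level,
            min_unique_peptides=config.min_unique_peptides,
            medium=medium,
        )
        for medium in ("control", "cm")
    }
    presence = proteomics.classify_presence(catalogs["control"], catalogs["cm"])
    for medium, cat in catalogs.items():
        cat.to_tsv(out / f"catalog_{medium}.tsv")
    report["stages"]["proteomics"] = {
        "n_psms": len(psms),
        "score_threshold": {m: c.score_threshold for m, c in catalogs.items()},
        "accepted": {m: len(c.accepted_ids) for m, c in catalogs.items()},
    }

    # -- stage 2: expression ------------------------------------------------
    cyto = expression.read_cytokine_table(config.cytokines)
    ct = expression.read_ct_table(config.ct)
    cyto_fc = expression.cytokine_fold_changes(
        cyto, config.treated_condition, config.control_condition
    )
    ct_fc = expression.ct_fold_changes(
        ct, config.housekeeping_gene,
        config.treated_condition, config.control_condition,
    )
    diff_cyto, cyto_fc = expression.call_differential(
        cyto_fc, config.log2fc_threshold, config.p_threshold
    )
    diff_ct, ct_fc = expression.call_differential(
        ct_fc, config.log2fc_threshold, config.p_threshold
    )
    cyto_fc.to_csv(out / "cytokine_fold_changes.tsv", sep="\t", index=False)
    ct_fc.to_csv(out / "ct_fold_changes.tsv", sep="\t", index=False)
    expression.export_heatmap(
        expression.heatmap_matrix(cyto_fc), out / "cytokine_heatmap.tsv"
    )
    differential_features = expression.pool_features(diff_cyto) | (
        expression.pool_features(diff_ct)
    )
    panel_membership: dict[str, set[str]] = {}
    for analyte in cyto["analyte"].unique():
        panel_membership.setdefault(str(analyte), set()).add("cytokine")
    for gene in set(ct["gene"]) - {config.housekeeping_gene}:
        panel_membership.setdefault(str(gene), set()).add("pcr")
    report["stages"]["expression"] = {
        "n_differential_cytokine": len(diff_cyto),
        "n_differential_pcr": len(diff_ct),
        "differential_features": sorted(differential_features),
    }

    # -- stage 3: cytometry -------------------------------------------------
    events = cytometry.read_event_table(config.events)
    gate = (
        cytometry.GateConfig(thresholds=dict(config.gate_thresholds))
        if config.gate_thresholds
        else cytometry.GateConfig()
    )
    stats = cytometry.gate_and_classify(events, gate)
    stats.to_frame().to_csv(out / "populations.tsv", sep="\t", index=False)
    report["stages"]["cytometry"] = {
        "n_events": len(events),
        "n_classified": stats.total,
        "percentages": stats.percentages,
    }

    # -- stage 4: interactome ----------------------------------------------
    records = interactome.parse_biogrid_tab(
        Path(config.biogrid), taxon_filter=config.taxon,
        system_type=config.system_type,
    )
    mapping = interactome.read_id_mapping(config.id_mapping)
    records, unmapped = interactome.map_identifiers(records, mapping)
    # catalogs and presence map live in the accession namespace; translate
    sym_presence = {}
    for pid, cls in presence.items():
        sym, _ = interactome.apply_id_mapping([pid], mapping)
        sym_presence[sym[0]] = cls
    cm_symbols, _ = interactome.apply_id_mapping(
        sorted(catalogs["cm"].accepted_ids), mapping
    )
    graph = interactome.build_cm_network(records, set(cm_symbols))
    graph = interactome.expand_to_panel(
        graph, records, differential_features, panel_membership
    )
    graph = interactome.classify_nodes(graph, sym_presence, panel_membership)
    candidates = interactome.select_mediators(
        graph, panel_membership, config.min_measured_degree
    )
    paths = interactome.export_network(graph, candidates, out)
    selected = [c.protein_id for c in candidates if c.selected]
    report["stages"]["interactome"] = {
        "n_records": len(records),
        "n_unmapped_ids": len(unmapped),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_candidates": len(candidates),
        "selected": selected,
    }
    logger.info("selected mediators: %s", selected)

    # -- provenance & report -------------------------------------------------
    report["candidates"] = [dataclasses.asdict(c) for c in candidates]
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "report.json":
            report["provenance"]["outputs"][p.name] = _sha256(p)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def run_demo(
    seed: int = 0,
    outdir: str | Path = "demo_out",
    config: synthetic.SyntheticConfig | None = None,
    **pipeline_overrides,
) -> tuple[dict, synthetic.PlantedTruth]:
    """Generate a synthetic study and run the full pipeline on it.

    Returns (report, planted truth); the selected mediator set of a default
    run equals the planted hub set.
    """
    out = Path(outdir)
    syn = config or synthetic.SyntheticConfig(seed=seed)
    bundle = synthetic.generate_all(syn)
    paths = synthetic.write_bundle(bundle, out / "inputs")
    pipe = PipelineConfig(
        psms=str(paths["psms"]),
        id_mapping=str(paths["id_mapping"]),
        biogrid=str(paths["biogrid"]),
        cytokines=str(paths["cytokines"]),
        ct=str(paths["ct"]),
        events=str(paths["events"]),
        outdir=str(out / "results"),
        seed=seed,
        **pipeline_overrides,
    )
    report = run_pipeline(pipe)
    return report, bundle.truth
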