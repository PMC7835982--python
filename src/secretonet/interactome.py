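"""Interaction-network integration and hub-mediator selection.

The stage mirrors the three steps of the study design: (1) retrieve all
interactions between pairs of proteins identified in the conditioned medium,
(2) extend the network with the differentially expressed measured factors
(qPCR genes and multiplex cytokines) that interact with it, and (3) select
candidate mediators — proteins unique to the conditioned medium or panel
members — whose *measured degree*, the number of distinct differentially
expressed measured factors they touch, exceeds five.

Node annotation follows the network-figure convention: presence class
(diamond = unique to the conditioned medium, square = present in both media,
circle = panel factor detected in neither medium) and dataset class (blue =
qPCR panel, red = cytokine panel, purple = both, grey = neither).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .proteomics import SecretomeCatalog

__all__ = [
    "InteractionRecord",
    "MediatorCandidate",
    "parse_biogrid_tab",
    "write_biogrid_tab",
    "read_id_mapping",
    "map_identifiers",
    "apply_id_mapping",
    "build_cm_network",
    "expand_to_panel",
    "classify_nodes",
    "select_mediators",
    "export_network",
    "PRESENCE_SHAPES",
    "DATASET_COLORS",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "interactor_a", "interactor_b", "organism_a", "organism_b",
    "system_type", "source", "pubmed",
)

PRESENCE_SHAPES = {"unique_cm": "diamond", "shared": "square", "panel_only": "circle"}
DATASET_COLORS = {"pcr": "blue", "cytokine": "red", "both": "purple", "neither": "grey"}

# BioGRID TAB 2.0 column indices (0-based)
_COL_SYMBOL_A, _COL_SYMBOL_B = 7, 8
_COL_SYSTEM_TYPE, _COL_PUBMED = 12, 14
_COL_ORG_A, _COL_ORG_B, _COL_SOURCE = 15, 16, 23
_MIN_COLUMNS = 17


@dataclass(frozen=True)
class InteractionRecord:
    interactor_a: str
    interactor_b: str
    organism_a: str
    organism_b: str
    system_type: str
    source: str
    pubmed: str


def parse_biogrid_tab(
    source: str | Path | io.TextIOBase,
    taxon_filter: int | str | None = None,
    system_type: str | None = None,
) -> pd.DataFrame:
    """Parse BioGRID TAB 2.0 text into interaction records.

    Header lines (leading ``#`` or a column-name line) are tolerated.
    Malformed lines and self-interactions are skipped with a log entry; an
    optional taxon filter keeps records where both interactors match, and
    ``system_type`` restricts to physical or genetic evidence.
    """
    if isinstance(source, (str, Path)) and "\t" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    rows, skipped, self_loops = [], 0, 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#") or line.lower().startswith("biogrid interaction id"):
            continue
        fields = line.split("\t")
        if len(fields) < _MIN_COLUMNS:
            skipped += 1
            logger.warning("line %d: %d columns, skipped", lineno, len(fields))
            continue
        a, b = fields[_COL_SYMBOL_A].strip(), fields[_COL_SYMBOL_B].strip()
        if not a or not b or a == "-" or b == "-":
            skipped += 1
            logger.warning("line %d: missing interactor symbol, skipped", lineno)
            continue
        if a == b:
            self_loops += 1
            logger.info("line %d: self-interaction %s dropped", lineno, a)
            continue
        rows.append(
            (
                a, b, fields[_COL_ORG_A].strip(), fields[_COL_ORG_B].strip(),
                fields[_COL_SYSTEM_TYPE].strip().lower(),
                fields[_COL_SOURCE].strip() if len(fields) > _COL_SOURCE else "-",
                fields[_COL_PUBMED].strip(),
            )
        )
    if not rows:
        raise ValueError("no parseable interaction lines found")
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if taxon_filter is not None:
        taxon = str(taxon_filter)
        records = records.loc[
            (records["organism_a"] == taxon) & (records["organism_b"] == taxon)
        ].reset_index(drop=True)
    if system_type is not None:
        records = records.loc[
            records["system_type"] == system_type.lower()
        ].reset_index(drop=True)
    logger.info(
        "parsed %d interaction records (%d malformed, %d self-loops skipped)",
        len(records), skipped, self_loops,
    )
    return records


def write_biogrid_tab(records: pd.DataFrame, path: str | Path) -> None:
    """Serialize interaction records back to a minimal BioGRID TAB 2.0 file."""
    lines = [
        "#BioGRID Interaction ID\tEntrez Gene Interactor A\t"
        "Entrez Gene Interactor B\tBioGRID ID Interactor A\t"
        "BioGRID ID Interactor B\tSystematic Name Interactor A\t"
        "Systematic Name Interactor B\tOfficial Symbol Interactor A\t"
        "Official Symbol Interactor B\tSynonyms Interactor A\t"
        "Synonyms Interactor B\tExperimental System\tExperimental System Type\t"
        "Author\tPubmed ID\tOrganism Interactor A\tOrganism Interactor B\t"
        "Throughput\tScore\tModification\tPhenotypes\tQualifications\tTags\t"
        "Source Database"
    ]
    for n, rec in enumerate(records.itertuples(index=False), start=1):
        row = ["-"] * 24
        row[0] = str(n)
        row[_COL_SYMBOL_A] = rec.interactor_a
        row[_COL_SYMBOL_B] = rec.interactor_b
        row[_COL_SYSTEM_TYPE] = rec.system_type
        row[_COL_PUBMED] = rec.pubmed
        row[_COL_ORG_A] = rec.organism_a
        row[_COL_ORG_B] = rec.organism_b
        row[_COL_SOURCE] = rec.source
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

def read_id_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"accession", "symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"mapping table {path} lacks columns: {sorted(missing)}")
    return df


def _mapping_dict(mapping: pd.DataFrame) -> dict[str, str]:
    out: dict[str, str] = {}
    ambiguous = set()
    for acc, group in mapping.groupby("accession", sort=True):
        symbols = sorted(set(group["symbol"].astype(str)))
        if len(symbols) > 1:
            ambiguous.add(str(acc))
        out[str(acc)] = symbols[0]  # deterministic: lexicographic first
    if ambiguous:
        logger.warning(
            "%d accessions map to multiple symbols; resolved to the "
            "lexicographically first (e.g. %s)",
            len(ambiguous), sorted(ambiguous)[:3],
        )
    return out


def apply_id_mapping(ids, mapping: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Translate accessions to symbols; unmapped ids pass through verbatim.

    Returns (translated ids, unmapped ids) preserving input order.
    """
    table = _mapping_dict(mapping)
    translated, unmapped = [], []
    for i in ids:
        if str(i) in table:
            translated.append(table[str(i)])
        else:
            translated.append(str(i))
            unmapped.append(str(i))
    return translated, unmapped


def map_identifiers(
    records: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Remap interactor identifiers into the canonical (symbol) namespace."""
    out = records.copy()
    unmapped: list[str] = []
    for col in ("interactor_a", "interactor_b"):
        out[col], miss = apply_id_mapping(out[col].tolist(), mapping)
        unmapped.extend(miss)
    return out, sorted(set(unmapped))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_cm_network(
    records: pd.DataFrame, cm_catalog: SecretomeCatalog | set[str]
) -> nx.Graph:
    """Interactions between pairs of conditioned-medium proteins.

    Nodes are catalog proteins that have at least one qualifying edge; edges
    require BOTH endpoints in the catalog.  Duplicates and reversed pairs
    collapse onto single undirected edges.
    """
    cm_ids = (
        cm_catalog.accepted_ids
        if isinstance(cm_catalog, SecretomeCatalog)
        else set(cm_catalog)
    )
    graph = nx.Graph()
    if not cm_ids:
        logger.warning("empty conditioned-medium catalog: empty network")
        return graph
    for rec in records.itertuples(index=False):
        a, b = rec.interactor_a, rec.interactor_b
        if a != b and a in cm_ids and b in cm_ids:
            graph.add_edge(a, b)
    return graph


def expand_to_panel(
    graph: nx.Graph,
    records: pd.DataFrame,
    differential_features: set[str],
    panel_membership: dict[str, set[str]],
    include_panel_panel_edges: bool = False,
) -> nx.Graph:
    """Attach differentially expressed measured factors to the network.

    Adds an edge whenever a record joins a network protein to a factor in
    ``differential_features``; factors absent from the catalogs enter as new
    nodes.  Every node receives a ``measured_degree`` attribute: the number
    of distinct differentially expressed panel members adjacent to it.  Edges
    between two panel members are excluded unless
    ``include_panel_panel_edges`` — the procedure only anchors edges on
    conditioned-medium proteins.  The operation is idempotent.
    """
    out = graph.copy()
    anchors = set(graph.nodes)
    for rec in records.itertuples(index=False):
        a, b = rec.interactor_a, rec.interactor_b
        if a == b:
            continue
        a_diff, b_diff = a in differential_features, b in differential_features
        if a_diff and b_diff:
            # edges between two panel members are not anchored on a
            # conditioned-medium protein; excluded unless asked for
            if include_panel_panel_edges:
                out.add_edge(a, b)
        elif (a in anchors and b_diff) or (b in anchors and a_diff):
            out.add_edge(a, b)

    for node in out.nodes:
        measured = {
            nbr for nbr in out.neighbors(node) if nbr in differential_features
        }
        out.nodes[node]["measured_degree"] = len(measured)
        out.nodes[node]["measured_factors"] = sorted(measured)
    # total degree is the figure-style font-size attribute
    for node, degree in out.degree:
        out.nodes[node]["degree"] = degree
    _ = panel_membership  # classification uses it; kept in the signature for symmetry
    return out


def classify_nodes(
    graph: nx.Graph,
    presence_map: dict[str, str],
    panel_membership: dict[str, set[str]],
) -> nx.Graph:
    """Annotate every node with presence_class and dataset_class (total partitions).

    presence_class: unique_cm (diamond) / shared (square) / panel_only
    (circle, a panel factor detected in neither medium).  dataset_class: pcr
    (blue) / cytokine (red) / both (purple) / neither (grey).
    """
    contradictions = []
    for node in graph.nodes:
        presence = presence_map.get(node)
        assays = set(panel_membership.get(node, ()))
        if presence in ("unique_cm", "shared"):
            presence_class = presence
        elif presence is None and assays:
            presence_class = "panel_only"
        else:
            contradictions.append(node)
            continue
        if assays == {"pcr"}:
            dataset_class = "pcr"
        elif assays == {"cytokine"}:
            dataset_class = "cytokine"
        elif assays >= {"pcr", "cytokine"}:
            dataset_class = "both"
        else:
            dataset_class = "neither"
        graph.nodes[node]["presence_class"] = presence_class
        graph.nodes[node]["dataset_class"] = dataset_class
        graph.nodes[node]["shape"] = PRESENCE_SHAPES[presence_class]
        graph.nodes[node]["border_color"] = DATASET_COLORS[dataset_class]
    if contradictions:
        raise ValueError(
            "nodes with contradictory evidence (not in catalogs, not in panels, "
            f"or control-only yet present in the network): {sorted(contradictions)}"
        )
    return graph


# ---------------------------------------------------------------------------
# Mediator selection
# ---------------------------------------------------------------------------

@dataclass
class MediatorCandidate:
    """A protein with its measured degree and selection verdict."""

    protein_id: str
    measured_degree: int
    presence_class: str
    dataset_class: str
    selected: bool
    interacting_factors: list[tuple[str, str]]  # (factor, assay)


def select_mediators(
    graph: nx.Graph,
    panel_membership: dict[str, set[str]],
    min_measured_degree: int = 6,
) -> list[MediatorCandidate]:
    """Rank candidate mediators and select hubs touching >5 measured factors.

    Candidates are nodes that are either unique to the conditioned medium or
    members of a measurement panel; a candidate is selected when its measured
    degree reaches ``min_measured_degree`` (default 6, the strict reading of
    "more than five").  Ranking: measured degree descending, ties broken
    lexicographically by protein id.
    """
    candidates = []
    for node, attrs in graph.nodes(data=True):
        if "presence_class" not in attrs:
            raise ValueError(f"node {node!r} is unclassified; run classify_nodes")
        in_panel = node in panel_membership
        if attrs["presence_class"] != "unique_cm" and not in_panel:
            continue
        factors = [
            (f, "/".join(sorted(panel_membership.get(f, {"unknown"}))))
            for f in attrs.get("measured_factors", [])
        ]
        candidates.append(
            MediatorCandidate(
                protein_id=str(node),
                measured_degree=int(attrs.get("measured_degree", 0)),
                presence_class=attrs["presence_class"],
                dataset_class=attrs["dataset_class"],
                selected=attrs.get("measured_degree", 0) >= min_measured_degree,
                interacting_factors=factors,
            )
        )
    candidates.sort(key=lambda c: (-c.measured_degree, c.protein_id))
    return candidates


def candidates_frame(candidates: list[MediatorCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in candidates],
            "measured_degree": [c.measured_degree for c in candidates],
            "presence_class": [c.presence_class for c in candidates],
            "dataset_class": [c.dataset_class for c in candidates],
            "selected": [c.selected for c in candidates],
            "interacting_factors": [
                ";".join(f"{f}[{a}]" for f, a in c.interacting_factors)
                for c in candidates
            ],
        }
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(
    graph: nx.Graph,
    candidates: list[MediatorCandidate],
    outdir: str | Path,
    basename: str = "network",
) -> dict[str, Path]:
    """Write GraphML + SIF + node-attribute TSV (+ candidate table)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": out / f"{basename}.graphml",
        "sif": out / f"{basename}.sif",
        "nodes": out / f"{basename}.nodes.tsv",
        "candidates": out / f"{basename}.candidates.tsv",
    }
    selected = {c.protein_id for c in candidates if c.selected}

    g = graph.copy()
    for node in g.nodes:
        g.nodes[node]["selected"] = node in selected
        g.nodes[node].pop("measured_factors", None)  # lists are not GraphML scalars
    nx.write_graphml(g, paths["graphml"])

    with open(paths["sif"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\tinteracts\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")

    rows = []
    for node, attrs in sorted(graph.nodes(data=True)):
        rows.append(
            (
                node,
                attrs.get("presence_class", ""),
                attrs.get("shape", ""),
                attrs.get("dataset_class", ""),
                attrs.get("border_color", ""),
                attrs.get("degree", graph.degree(node)),
                attrs.get("measured_degree", 0),
                node in selected,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "protein_id", "presence_class", "shape", "dataset_class",
            "border_color", "degree", "measured_degree", "selected",
        ],
    ).to_csv(paths["nodes"], sep="\t", index=False)
    candidates_frame(candidates).to_csv(paths["candidates"], sep="\t", index=False)
    return paths
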