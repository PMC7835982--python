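"""Synthetic assay data with planted ground truth.

Every pipeline input — PSM tables, a BioGRID-style interaction file, multiplex
cytokine concentrations, qPCR Ct values and flow-cytometry event tables — can
be generated from a single :class:`SyntheticConfig`.  The generators plant a
known structure (hub proteins wired to more than five differentially expressed
measured factors, known log2 fold changes, a computable score threshold for
the target-decoy filter, known subpopulation fractions) and record it in a
:class:`PlantedTruth` sidecar, so downstream stages can be tested end to end
without any external data.

Score model: target PSM scores ~ Normal(mu_t, sd), decoy scores ~
Normal(mu_d, sd) with mu_t > mu_d.  Concentrations carry multiplicative
log-normal noise (they must stay positive); Ct values carry additive Gaussian
noise on the cycle scale.  Each generator is a pure function of
(seed, config): identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SyntheticConfig",
    "SyntheticConfigError",
    "PlantedTruth",
    "SyntheticBundle",
    "CYTOKINE_PANEL",
    "QPCR_PANEL",
    "HOUSEKEEPING_GENE",
    "COMBO_LABELS",
    "default_planted_log2fc",
    "default_population_fractions",
    "generate_psm_table",
    "generate_id_mapping",
    "generate_interaction_db",
    "generate_cytokine_panel",
    "generate_ct_table",
    "generate_cytometry_events",
    "generate_all",
    "write_bundle",
]

#: Gene symbols of the 40 analytes of a human 40-plex chemokine panel.
CYTOKINE_PANEL: tuple[str, ...] = (
    "CCL1", "CCL2", "CCL3", "CCL7", "CCL8", "CCL11", "CCL13", "CCL15",
    "CCL17", "CCL19", "CCL20", "CCL21", "CCL22", "CCL23", "CCL24", "CCL25",
    "CCL26", "CCL27", "CX3CL1", "CXCL1", "CXCL2", "CXCL5", "CXCL6", "CXCL8",
    "CXCL9", "CXCL10", "CXCL11", "CXCL12", "CXCL13", "CXCL16", "CSF2",
    "IFNG", "IL1B", "IL2", "IL4", "IL6", "IL10", "IL16", "MIF", "TNF",
)

#: qPCR panel: polarization / remodeling markers plus the 18S housekeeping gene.
QPCR_PANEL: tuple[str, ...] = ("PDGFB", "TIMP1", "PTGS2", "MRC1")
HOUSEKEEPING_GENE = "RN18S"

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: The eight CD163/CD206/CD80 marker combinations, CD163 varying slowest.
COMBO_LABELS: tuple[str, ...] = tuple(
    f"CD163{a}/CD206{b}/CD80{c}"
    for a in "+-" for b in "+-" for c in "+-"
)

# rng stream offsets so the five generators are mutually independent
_STREAM_PSM, _STREAM_NET, _STREAM_CYTO, _STREAM_CT, _STREAM_FLOW = range(5)


class SyntheticConfigError(ValueError):
    """A SyntheticConfig field is out of its valid range (named in args)."""


def default_planted_log2fc() -> dict[str, dict[str, float]]:
    """Planted log2 fold changes (treated vs control) per feature and subtype.

    The pattern mirrors the qualitative biology of conditioned-medium treated
    macrophages: broad cytokine down-regulation in M1, up-regulation in M2/M2a,
    and remodeling-gene shifts in M2a.  Magnitudes are at least 1.5 log2 units
    for differential features so a |log2fc| >= 1 call is stable under the
    default measurement noise; TIMP1 carries a deliberately sub-threshold
    effect to exercise the non-differential path.
    """
    return {
        "CSF2": {"M1": -2.5, "M2a": 1.5},
        "CCL23": {"M1": -2.0},
        "CCL25": {"M1": -2.0, "M2": 1.5},
        "CCL15": {"M1": -1.8},
        "CCL3": {"M1": -1.5},
        "CCL1": {"M2": 2.0},
        "CXCL12": {"M2": 1.8, "M2c": -1.5},
        "IL6": {"M2a": 2.5, "M2b": 1.5},
        "CXCL2": {"M2a": 2.0},
        "CCL8": {"M2a": 2.0, "M2b": 1.5},
        "CXCL8": {"M2a": 1.8, "M2b": 1.5},
        "CCL2": {"M2a": 1.5, "M2b": 1.5},
        "CXCL16": {"M2b": 1.5},
        "CXCL5": {"M2b": 1.5},
        # qPCR features (M2a focus)
        "PDGFB": {"M2a": 1.5},
        "PTGS2": {"M2a": 1.5},
        "MRC1": {"M2a": -1.5},
        "TIMP1": {"M2a": 0.3},
    }


def default_population_fractions() -> dict[str, float]:
    """Planted fractions of viable CD68+ events over the eight combos."""
    return {
        "CD163+/CD206+/CD80+": 0.20,
        "CD163+/CD206+/CD80-": 0.15,
        "CD163+/CD206-/CD80+": 0.10,
        "CD163+/CD206-/CD80-": 0.15,
        "CD163-/CD206+/CD80+": 0.10,
        "CD163-/CD206+/CD80-": 0.15,
        "CD163-/CD206-/CD80+": 0.05,
        "CD163-/CD206-/CD80-": 0.10,
    }


@dataclass
class SyntheticConfig:
    """Parameters of the planted study conditions.

    Counts describe the secretome: ``n_cm_proteins`` proteins found only in the
    conditioned medium, ``n_control_proteins`` only in the control medium and
    ``n_shared_proteins`` in both.  Hub structure is separable by construction:
    planted hubs touch at least ``hub_min_measured_degree`` differentially
    expressed measured factors, every other conditioned-medium protein at most
    ``nonhub_max_measured_degree``.
    """

    seed: int = 0
    # proteome composition
    n_cm_proteins: int = 60
    n_control_proteins: int = 20
    n_shared_proteins: int = 20
    # planted network structure
    n_planted_hubs: int = 2
    hub_min_measured_degree: int = 6
    nonhub_max_measured_degree: int = 5
    n_background_edges: int = 120
    n_distractor_edges: int = 10
    # measurement panels
    n_cytokines: int = 40
    subtypes: tuple[str, ...] = ("M0", "M1", "M2", "M2a", "M2b", "M2c")
    n_replicates: int = 4
    planted_log2fc: dict[str, dict[str, float]] = field(
        default_factory=default_planted_log2fc
    )
    treated_condition: str = "ipsc_cm"
    control_condition: str = "control"
    # noise levels
    ct_noise_sd: float = 0.15          # cycles, additive
    concentration_cv: float = 0.15     # fraction, multiplicative
    # PSM score model
    decoy_fraction: float = 0.3
    n_psms: int = 4000
    target_score_mean: float = 30.0
    decoy_score_mean: float = 12.0
    score_sd: float = 5.0
    fdr_level: float = 0.01
    # cytometry
    n_events: int = 40_000
    nonviable_fraction: float = 0.10
    cd68_negative_fraction: float = 0.05
    true_population_fractions: dict[str, float] = field(
        default_factory=default_population_fractions
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            "n_cm_proteins", "n_control_proteins", "n_shared_proteins",
            "n_planted_hubs", "n_background_edges", "n_distractor_edges",
            "n_cytokines", "n_replicates", "n_psms", "n_events",
        )
        for name in counts:
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        if self.n_planted_hubs > self.n_cm_proteins + self.n_shared_proteins:
            raise SyntheticConfigError(
                "n_planted_hubs exceeds the number of conditioned-medium proteins"
            )
        if self.hub_min_measured_degree <= self.nonhub_max_measured_degree:
            raise SyntheticConfigError(
                "hub_min_measured_degree must exceed nonhub_max_measured_degree"
            )
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise SyntheticConfigError("decoy_fraction must lie in [0, 1)")
        if self.concentration_cv <= 0:
            raise SyntheticConfigError("concentration_cv must be positive")
        if self.ct_noise_sd < 0:
            raise SyntheticConfigError("ct_noise_sd must be >= 0")
        if self.target_score_mean <= self.decoy_score_mean:
            raise SyntheticConfigError(
                "target_score_mean must exceed decoy_score_mean"
            )
        if self.score_sd <= 0:
            raise SyntheticConfigError("score_sd must be positive")
        if not 0.0 < self.fdr_level < 1.0:
            raise SyntheticConfigError("fdr_level must lie in (0, 1)")
        if not 0.0 <= self.nonviable_fraction < 1.0:
            raise SyntheticConfigError("nonviable_fraction must lie in [0, 1)")
        if self.n_cytokines > len(CYTOKINE_PANEL):
            raise SyntheticConfigError(
                f"n_cytokines cannot exceed {len(CYTOKINE_PANEL)}"
            )
        total = math.fsum(self.true_population_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"true_population_fractions must sum to 1 (got {total!r})"
            )
        unknown = set(self.true_population_fractions) - set(COMBO_LABELS)
        if unknown:
            raise SyntheticConfigError(
                f"true_population_fractions has unknown combos: {sorted(unknown)}"
            )

    # ---- derived vocabulary -------------------------------------------------

    @property
    def cytokines(self) -> tuple[str, ...]:
        return CYTOKINE_PANEL[: self.n_cytokines]

    @property
    def qpcr_genes(self) -> tuple[str, ...]:
        return QPCR_PANEL

    def protein_symbols(self) -> dict[str, list[str]]:
        """Synthetic protein symbols grouped by presence class.

        ``cm_only`` proteins are secreted only into the conditioned medium,
        ``shared`` into both media, ``control_only`` only into the control.
        """
        n1, n2, n3 = self.n_cm_proteins, self.n_shared_proteins, self.n_control_proteins
        syms = [f"P{i:04d}" for i in range(1, n1 + n2 + n3 + 1)]
        return {
            "cm_only": syms[:n1],
            "shared": syms[n1 : n1 + n2],
            "control_only": syms[n1 + n2 :],
        }

    def differential_features(self, threshold: float = 1.0) -> list[str]:
        """Features planted with |log2fc| >= threshold in any subtype."""
        out = []
        for feat, per_subtype in self.planted_log2fc.items():
            if any(abs(v) >= threshold for v in per_subtype.values()):
                out.append(feat)
        return sorted(out)

    def true_fdr_score_threshold(self) -> float:
        """Score t where the expected decoy/target ratio above t equals fdr_level.

        Solves d*S_d(t) / ((1-d)*S_t(t)) = alpha for the two planted normal
        survival functions; the planted separation guarantees a unique root.
        """
        d, a = self.decoy_fraction, self.fdr_level
        if d == 0.0:
            return -math.inf
        sd = self.score_sd

        def ratio(t: float) -> float:
            num = d * stats.norm.sf(t, self.decoy_score_mean, sd)
            den = (1.0 - d) * stats.norm.sf(t, self.target_score_mean, sd)
            return num / den - a

        lo = self.decoy_score_mean - 10 * sd
        hi = self.target_score_mean + 10 * sd
        return float(optimize.brentq(ratio, lo, hi))


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators; the oracle for all tests."""

    hub_proteins: set[str] = field(default_factory=set)
    true_fdr_score_threshold: float = math.nan
    true_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    true_population_fractions: dict[str, float] = field(default_factory=dict)
    differential_features: set[str] = field(default_factory=set)
    nonviable_fraction: float = math.nan

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hub_proteins": sorted(self.hub_proteins),
            "true_fdr_score_threshold": self.true_fdr_score_threshold,
            "true_log2fc": {
                f"{feat}|{sub}": v for (feat, sub), v in sorted(self.true_log2fc.items())
            },
            "true_population_fractions": self.true_population_fractions,
            "differential_features": sorted(self.differential_features),
            "nonviable_fraction": self.nonviable_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        log2fc = {}
        for key, v in payload["true_log2fc"].items():
            feat, sub = key.split("|", 1)
            log2fc[(feat, sub)] = v
        return cls(
            hub_proteins=set(payload["hub_proteins"]),
            true_fdr_score_threshold=payload["true_fdr_score_threshold"],
            true_log2fc=log2fc,
            true_population_fractions=payload["true_population_fractions"],
            differential_features=set(payload["differential_features"]),
            nonviable_fraction=payload["nonviable_fraction"],
        )


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.integers(8, 16, size=n)
    return ["".join(rng.choice(_AA, size=k)) for k in lengths]


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def generate_psm_table(config: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Scored peptide-spectrum matches for both media, with decoys.

    Each row is flagged decoy with probability ``decoy_fraction``.  Among the
    target rows, the first two per (protein, medium) pair carry distinct
    peptides whose scores are truncated above the planted threshold, so every
    generated protein is guaranteed to pass a two-peptide rule at the planted
    FDR level; remaining target rows are spread randomly over the proteome.
    """
    config.validate()
    rng = _rng(config, _STREAM_PSM)
    truth = PlantedTruth(
        true_fdr_score_threshold=config.true_fdr_score_threshold(),
        differential_features=set(config.differential_features()),
    )
    cols = ["peptide", "protein_id", "score", "is_decoy", "medium"]
    if config.n_psms == 0:
        return pd.DataFrame(columns=cols), truth

    groups = config.protein_symbols()
    accession = {s: f"ACC{s[1:]}" for g in groups.values() for s in g}
    # (accession, medium) pairs that must each receive two passing peptides
    guaranteed: list[tuple[str, str]] = []
    for sym in groups["cm_only"]:
        guaranteed.append((accession[sym], "cm"))
    for sym in groups["shared"]:
        guaranteed.append((accession[sym], "cm"))
        guaranteed.append((accession[sym], "control"))
    for sym in groups["control_only"]:
        guaranteed.append((accession[sym], "control"))

    is_decoy = rng.random(config.n_psms) < config.decoy_fraction
    n_targets = int((~is_decoy).sum())
    need = 2 * len(guaranteed)
    if n_targets < need:
        raise SyntheticConfigError(
            f"n_psms too small: {n_targets} target PSMs drawn but "
            f"{need} needed to guarantee two peptides per protein"
        )

    t_star = truth.true_fdr_score_threshold
    mu_t, mu_d, sd = config.target_score_mean, config.decoy_score_mean, config.score_sd

    protein_ids = np.empty(config.n_psms, dtype=object)
    media = np.empty(config.n_psms, dtype=object)
    scores = np.empty(config.n_psms)
    peptides = np.array(_random_peptides(rng, config.n_psms), dtype=object)

    target_rows = np.flatnonzero(~is_decoy)
    decoy_rows = np.flatnonzero(is_decoy)

    # guaranteed two passing peptides per (protein, medium)
    a_trunc = (t_star - mu_t) / sd
    for k, (acc, medium) in enumerate(guaranteed):
        rows = target_rows[2 * k : 2 * k + 2]
        protein_ids[rows] = acc
        media[rows] = medium
        scores[rows] = stats.truncnorm.rvs(
            a_trunc, np.inf, loc=mu_t, scale=sd, size=2, random_state=rng
        )
        # two distinct peptides per protein by construction
        while peptides[rows[0]] == peptides[rows[1]]:  # pragma: no cover
            peptides[rows[1]] = _random_peptides(rng, 1)[0]

    # remaining target rows: random protein from its valid media
    rest = target_rows[need:]
    if rest.size:
        pick = rng.integers(0, len(guaranteed), size=rest.size)
        for row, j in zip(rest, pick):
            protein_ids[row], media[row] = guaranteed[j]
        scores[rest] = rng.normal(mu_t, sd, size=rest.size)

    if decoy_rows.size:
        protein_ids[decoy_rows] = [
            f"DECOY_{i:05d}" for i in rng.integers(0, max(need, 1), size=decoy_rows.size)
        ]
        media[decoy_rows] = rng.choice(["cm", "control"], size=decoy_rows.size)
        scores[decoy_rows] = rng.normal(mu_d, sd, size=decoy_rows.size)

    psms = pd.DataFrame(
        {
            "peptide": peptides,
            "protein_id": protein_ids,
            "score": np.round(scores, 4),
            "is_decoy": is_decoy,
            "medium": media,
        }
    )
    return psms, truth


def generate_id_mapping(config: SyntheticConfig) -> pd.DataFrame:
    """Accession <-> symbol pairs joining the LC-MS and network namespaces."""
    groups = config.protein_symbols()
    symbols = [s for g in groups.values() for s in g]
    return pd.DataFrame(
        {"accession": [f"ACC{s[1:]}" for s in symbols], "symbol": symbols}
    )


# ---------------------------------------------------------------------------
# Interaction database
# ---------------------------------------------------------------------------

_BIOGRID_COLUMNS = (
    "#BioGRID Interaction ID", "Entrez Gene Interactor A",
    "Entrez Gene Interactor B", "BioGRID ID Interactor A",
    "BioGRID ID Interactor B", "Systematic Name Interactor A",
    "Systematic Name Interactor B", "Official Symbol Interactor A",
    "Official Symbol Interactor B", "Synonyms Interactor A",
    "Synonyms Interactor B", "Experimental System",
    "Experimental System Type", "Author", "Pubmed ID",
    "Organism Interactor A", "Organism Interactor B", "Throughput",
    "Score", "Modification", "Phenotypes", "Qualifications", "Tags",
    "Source Database",
)


def generate_interaction_db(
    config: SyntheticConfig,
    cm_ids: list[str] | None = None,
    panel_ids: list[str] | None = None,
) -> tuple[str, set[str]]:
    """BioGRID TAB 2.0 text with planted hub wiring; returns (text, hub set).

    Each planted hub is connected to at least ``hub_min_measured_degree``
    distinct differentially expressed panel members; every other
    conditioned-medium protein to at most ``nonhub_max_measured_degree``.
    A sparse ring plus random background edges connect the conditioned-medium
    proteins among themselves, and a few distractor edges involve proteins
    outside every catalog to exercise the network filter.
    """
    config.validate()
    rng = _rng(config, _STREAM_NET)
    groups = config.protein_symbols()
    if cm_ids is None:
        cm_ids = groups["cm_only"] + groups["shared"]
    if panel_ids is None:
        panel_ids = config.differential_features()
    cm_ids = sorted(cm_ids)
    panel_ids = sorted(panel_ids)

    n_hubs = config.n_planted_hubs
    if n_hubs > 0 and not panel_ids:
        raise SyntheticConfigError("panel_ids is empty but n_planted_hubs > 0")
    if n_hubs > 0 and len(panel_ids) < config.hub_min_measured_degree:
        raise SyntheticConfigError(
            "hub_min_measured_degree infeasible: panel has "
            f"{len(panel_ids)} differential members"
        )
    # hubs must be selectable downstream: the selection rule admits only
    # proteins unique to the conditioned medium (or panel members), so plant
    # hubs among cm-only proteins whenever any are in the pool
    hub_pool = sorted(set(groups["cm_only"]) & set(cm_ids)) or cm_ids
    if n_hubs > len(hub_pool):
        raise SyntheticConfigError(
            "n_planted_hubs exceeds the number of selectable hub candidates"
        )
    hubs = (
        set(map(str, rng.choice(hub_pool, size=n_hubs, replace=False)))
        if n_hubs
        else set()
    )

    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((min(a, b), max(a, b)))

    # hub wiring: draw a degree comfortably above the cut so that noisy
    # differential calls downstream cannot drop a hub below it
    lo = min(config.hub_min_measured_degree + 3, len(panel_ids))
    for hub in sorted(hubs):
        k = int(rng.integers(lo, len(panel_ids) + 1))
        for factor in rng.choice(panel_ids, size=k, replace=False):
            add(hub, str(factor))

    # non-hub wiring: at most nonhub_max_measured_degree panel neighbours
    for prot in cm_ids:
        if prot in hubs:
            continue
        cap = min(config.nonhub_max_measured_degree, len(panel_ids))
        k = int(rng.integers(0, cap + 1))
        if k:
            for factor in rng.choice(panel_ids, size=k, replace=False):
                add(prot, str(factor))

    # conditioned-medium backbone: ring + random background edges
    for i, prot in enumerate(cm_ids):
        add(prot, cm_ids[(i + 1) % len(cm_ids)])
    for _ in range(config.n_background_edges):
        a, b = rng.choice(cm_ids, size=2, replace=False)
        add(a, b)

    # distractors: proteins in no catalog and no panel
    strangers = [f"X{i:04d}" for i in range(1, config.n_distractor_edges + 1)]
    for i, s in enumerate(strangers):
        if i % 2 == 0 and cm_ids:
            add(s, str(rng.choice(cm_ids)))
        elif len(strangers) > 1:
            add(s, strangers[(i + 1) % len(strangers)])

    lines = ["\t".join(_BIOGRID_COLUMNS)]
    for n, (a, b) in enumerate(sorted(edges), start=1):
        system_type = "physical" if rng.random() < 0.9 else "genetic"
        system = "Two-hybrid" if system_type == "physical" else "Synthetic Lethality"
        row = [
            str(n), "-", "-", str(100000 + n), str(200000 + n), "-", "-",
            a, b, "-", "-", system, system_type, "Synthetic (2026)",
            str(30000000 + n), "9606", "9606", "Low Throughput", "-", "-",
            "-", "-", "-", "SYNTHETIC",
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n", hubs


# ---------------------------------------------------------------------------
# Cytokine panel and Ct tables
# ---------------------------------------------------------------------------

def _planted_log2fc_for(config: SyntheticConfig, feature: str, subtype: str) -> float:
    return config.planted_log2fc.get(feature, {}).get(subtype, 0.0)


def generate_cytokine_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Multiplex cytokine concentrations (pg/mL) per analyte/subtype/condition.

    Treated-condition means are the control means scaled by 2**log2fc; each
    replicate carries multiplicative log-normal noise with the configured CV.
    """
    config.validate()
    unknown = set(config.planted_log2fc) - set(config.cytokines) - set(
        config.qpcr_genes
    ) - {HOUSEKEEPING_GENE}
    if unknown:
        raise SyntheticConfigError(
            f"planted_log2fc keys outside both panels: {sorted(unknown)}"
        )
    rng = _rng(config, _STREAM_CYTO)
    sigma = math.sqrt(math.log1p(config.concentration_cv**2))
    rows = []
    for analyte in config.cytokines:
        for subtype in config.subtypes:
            base = 10.0 ** rng.uniform(1.0, 3.0)  # 10 - 1000 pg/mL
            fc = 2.0 ** _planted_log2fc_for(config, analyte, subtype)
            for condition, mean in (
                (config.control_condition, base),
                (config.treated_condition, base * fc),
            ):
                noise = rng.normal(0.0, sigma, size=config.n_replicates)
                for rep, eps in enumerate(noise, start=1):
                    rows.append(
                        (analyte, subtype, condition, rep, mean * math.exp(eps))
                    )
    return pd.DataFrame(
        rows, columns=["analyte", "subtype", "condition", "replicate", "concentration"]
    )


def generate_ct_table(config: SyntheticConfig) -> pd.DataFrame:
    """qPCR cycle-threshold values; Ct = baseline - log2(relative expression).

    The housekeeping gene carries no planted effect in any condition, so the
    planted log2 fold change of a gene appears downstream as ddCt = -log2fc.
    """
    config.validate()
    rng = _rng(config, _STREAM_CT)
    genes = list(config.qpcr_genes) + [HOUSEKEEPING_GENE]
    rows = []
    for gene in genes:
        for subtype in config.subtypes:
            base = 14.0 if gene == HOUSEKEEPING_GENE else rng.uniform(18.0, 28.0)
            planted = 0.0 if gene == HOUSEKEEPING_GENE else _planted_log2fc_for(
                config, gene, subtype
            )
            for condition, shift in (
                (config.control_condition, 0.0),
                (config.treated_condition, -planted),
            ):
                noise = rng.normal(0.0, config.ct_noise_sd, size=config.n_replicates)
                for rep, eps in enumerate(noise, start=1):
                    rows.append((gene, subtype, condition, rep, base + shift + eps))
    return pd.DataFrame(
        rows, columns=["gene", "subtype", "condition", "replicate", "ct"]
    )


# ---------------------------------------------------------------------------
# Flow cytometry events
# ---------------------------------------------------------------------------

# log-intensity means of the negative and positive staining components;
# five log-sds separate both from the default gate at 1000 a.u.
_LOW_LOG_MEAN, _HIGH_LOG_MEAN, _LOG_SD = math.log(120.0), math.log(9000.0), 0.4


def generate_cytometry_events(config: SyntheticConfig) -> pd.DataFrame:
    """Per-event fluorescence intensities for CD68/CD80/CD163/CD206/7-AAD.

    Viable events are assigned a marker combo by the planted fractions; a
    ``nonviable_fraction`` of events is 7-AAD high and a small fraction is
    CD68 negative.  Intensities are drawn from well-separated log-normal
    high/low components, so fixed-threshold gating is robust.
    """
    config.validate()
    rng = _rng(config, _STREAM_FLOW)
    n = config.n_events
    combos = sorted(config.true_population_fractions)
    probs = np.array([config.true_population_fractions[c] for c in combos])
    combo_idx = rng.choice(len(combos), size=n, p=probs / probs.sum())
    nonviable = rng.random(n) < config.nonviable_fraction
    cd68_neg = rng.random(n) < config.cd68_negative_fraction

    def intensity(positive: np.ndarray) -> np.ndarray:
        mu = np.where(positive, _HIGH_LOG_MEAN, _LOW_LOG_MEAN)
        return np.exp(rng.normal(mu, _LOG_SD))

    marker_state = {m: np.zeros(n, dtype=bool) for m in ("CD163", "CD206", "CD80")}
    for i, combo in enumerate(combos):
        mask = combo_idx == i
        for part in combo.split("/"):
            marker, sign = part[:-1], part[-1]
            if sign == "+":
                marker_state[marker] |= mask

    return pd.DataFrame(
        {
            "event_id": np.arange(1, n + 1),
            "CD68": intensity(~cd68_neg),
            "CD80": intensity(marker_state["CD80"]),
            "CD163": intensity(marker_state["CD163"]),
            "CD206": intensity(marker_state["CD206"]),
            "7AAD": intensity(nonviable),
        }
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """All five generated inputs plus the planted-truth sidecar."""

    psms: pd.DataFrame
    id_mapping: pd.DataFrame
    biogrid_text: str
    cytokines: pd.DataFrame
    ct: pd.DataFrame
    events: pd.DataFrame
    truth: PlantedTruth
    config: SyntheticConfig


def generate_all(config: SyntheticConfig) -> SyntheticBundle:
    """Generate every pipeline input and assemble the complete PlantedTruth."""
    psms, truth = generate_psm_table(config)
    biogrid_text, hubs = generate_interaction_db(config)
    truth.hub_proteins = hubs
    truth.true_population_fractions = dict(config.true_population_fractions)
    truth.nonviable_fraction = config.nonviable_fraction
    for feat, per_subtype in config.planted_log2fc.items():
        for subtype, v in per_subtype.items():
            truth.true_log2fc[(feat, subtype)] = v
    return SyntheticBundle(
        psms=psms,
        id_mapping=generate_id_mapping(config),
        biogrid_text=biogrid_text,
        cytokines=generate_cytokine_panel(config),
        ct=generate_ct_table(config),
        events=generate_cytometry_events(config),
        truth=truth,
        config=config,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all inputs as TSV / TAB 2.0 / JSON files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": out / "psms.tsv",
        "id_mapping": out / "id_mapping.tsv",
        "biogrid": out / "interactions.tab2.txt",
        "cytokines": out / "cytokines.tsv",
        "ct": out / "ct.tsv",
        "events": out / "events.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    bundle.psms.to_csv(paths["psms"], sep="\t", index=False)
    bundle.id_mapping.to_csv(paths["id_mapping"], sep="\t", index=False)
    paths["biogrid"].write_text(bundle.biogrid_text)
    bundle.cytokines.to_csv(paths["cytokines"], sep="\t", index=False)
    bundle.ct.to_csv(paths["ct"], sep="\t", index=False)
    bundle.events.to_csv(paths["events"], sep="\t", index=False, float_format="%.3f")
    bundle.truth.to_json(paths["truth"])
    cfg = dataclasses.asdict(bundle.config)
    cfg["subtypes"] = list(cfg["subtypes"])
    paths["config"].write_text(json.dumps(cfg, indent=2, default=str) + "\n")
    return paths
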