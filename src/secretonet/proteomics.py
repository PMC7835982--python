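"""Secretome cataloguing from scored peptide-spectrum matches.

Given a table of PSMs with target/decoy flags, a score threshold is set so
that the decoy/target ratio among records at or above it does not exceed the
requested false-discovery-rate level (1% by default).  A protein enters the
catalog of its medium when at least two distinct peptide sequences pass the
threshold (the two-peptide rule); its abundance is summarized as the peptide
match score summation (PMSS), the sum of search-engine scores of all its
above-threshold target PSMs.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SecretomeCatalog",
    "read_psm_table",
    "normalize_peptide",
    "estimate_fdr_threshold",
    "build_catalog",
    "classify_presence",
]

logger = logging.getLogger(__name__)

PSM_COLUMNS = ("peptide", "protein_id", "score", "is_decoy", "medium")

_NON_RESIDUE = re.compile(r"[^A-Z]")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM TSV (peptide, protein_id, score, is_decoy, medium)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table {path} lacks columns: {sorted(missing)}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def normalize_peptide(peptide: str) -> str:
    """Canonical peptide sequence: uppercase, modification annotations stripped.

    Anything that is not an uppercase letter after case-folding — mass tags
    such as ``[+57.02]``, ``(ox)`` markers, terminal dots — is removed, so
    modified forms of the same sequence count as one unique peptide.
    """
    return _NON_RESIDUE.sub("", str(peptide).upper())


def estimate_fdr_threshold(psms: pd.DataFrame, fdr_level: float = 0.01) -> float:
    """Smallest score t with (#decoys >= t) / (#targets >= t) <= fdr_level.

    Candidates are the observed scores.  Returns ``+inf`` when no observed
    cutoff satisfies the level (nothing is accepted); raises when the table
    has no decoys (the ratio is not estimable) or no targets.
    """
    if not 0.0 < fdr_level <= 1.0:
        raise ValueError("fdr_level must lie in (0, 1]")
    decoy_scores = np.sort(psms.loc[psms["is_decoy"], "score"].to_numpy(float))
    target_scores = np.sort(psms.loc[~psms["is_decoy"], "score"].to_numpy(float))
    if decoy_scores.size == 0:
        raise ValueError("FDR not estimable: PSM table contains no decoy records")
    if target_scores.size == 0:
        raise ValueError("FDR not estimable: PSM table contains no target records")

    candidates = np.unique(np.concatenate([decoy_scores, target_scores]))
    n_decoys = decoy_scores.size - np.searchsorted(decoy_scores, candidates, "left")
    n_targets = target_scores.size - np.searchsorted(target_scores, candidates, "left")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_targets > 0, n_decoys / np.maximum(n_targets, 1), np.inf)
    ok = np.flatnonzero(ratio <= fdr_level)
    if ok.size == 0:
        logger.warning(
            "no score cutoff reaches FDR <= %g; zero acceptances", fdr_level
        )
        return math.inf
    return float(candidates[ok[0]])


@dataclass
class SecretomeCatalog:
    """Accepted proteins of one medium with PMSS abundances."""

    medium: str
    proteins: pd.DataFrame  # protein_id, medium, unique_peptides, pmss, accepted
    fdr_level: float = 0.01
    score_threshold: float | dict[str, float] = math.nan
    min_unique_peptides: int = 2
    n_psms_read: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0 and self.fdr_level != 1.0:
            raise ValueError("fdr_level must lie in (0, 1]")

    @property
    def accepted_ids(self) -> set[str]:
        mask = self.proteins["accepted"]
        return set(self.proteins.loc[mask, "protein_id"])

    def pmss(self, protein_id: str) -> float:
        row = self.proteins.loc[self.proteins["protein_id"] == protein_id]
        if row.empty:
            raise KeyError(protein_id)
        return float(row["pmss"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.proteins.to_csv(path, sep="\t", index=False)


def _threshold_input(psms: pd.DataFrame, fdr_unit: str) -> pd.DataFrame:
    if fdr_unit == "psm":
        return psms
    if fdr_unit == "peptide":
        # best score per (normalized peptide, decoy status)
        key = psms["peptide"].map(normalize_peptide)
        idx = (
            psms.assign(_pep=key)
            .groupby(["_pep", "is_decoy"], sort=False)["score"]
            .idxmax()
        )
        return psms.loc[idx]
    raise ValueError(f"fdr_unit must be 'psm' or 'peptide', got {fdr_unit!r}")


def build_catalog(
    psms: pd.DataFrame,
    fdr_level: float = 0.01,
    min_unique_peptides: int = 2,
    medium: str | None = None,
    fdr_unit: str = "psm",
) -> SecretomeCatalog:
    """Apply the FDR threshold and the two-peptide rule to one medium's PSMs.

    A protein is accepted iff it has at least ``min_unique_peptides`` distinct
    normalized peptide sequences with score at or above the threshold and is
    not a decoy.  PMSS is the sum of scores of all its above-threshold target
    PSMs.  When a ``mode`` column is present (e.g. CID/ETD spectra scored
    separately), a threshold is estimated per mode and records are pooled
    after thresholding.
    """
    if medium is not None:
        psms = psms.loc[psms["medium"] == medium]
    else:
        media = psms["medium"].unique() if len(psms) else []
        if len(media) > 1:
            raise ValueError(
                f"PSM table mixes media {sorted(media)}; pass medium= explicitly"
            )
        medium = str(media[0]) if len(media) else "unknown"

    empty = pd.DataFrame(
        columns=["protein_id", "medium", "unique_peptides", "pmss", "accepted"]
    )
    if psms.empty:
        logger.warning("empty PSM table for medium %r: empty catalog", medium)
        return SecretomeCatalog(medium, empty, fdr_level, math.inf,
                                min_unique_peptides, 0)

    if "mode" in psms.columns:
        parts, thresholds = [], {}
        for mode, sub in psms.groupby("mode", sort=True):
            t = estimate_fdr_threshold(_threshold_input(sub, fdr_unit), fdr_level)
            thresholds[str(mode)] = t
            parts.append(sub.loc[sub["score"] >= t])
        passing = pd.concat(parts) if parts else psms.iloc[0:0]
        threshold: float | dict[str, float] = thresholds
    else:
        threshold = estimate_fdr_threshold(_threshold_input(psms, fdr_unit), fdr_level)
        passing = psms.loc[psms["score"] >= threshold]

    targets = passing.loc[~passing["is_decoy"]].copy()
    if targets.empty:
        proteins = empty
    else:
        targets["peptide_norm"] = targets["peptide"].map(normalize_peptide)
        grouped = targets.groupby("protein_id", sort=True)
        proteins = pd.DataFrame(
            {
                "protein_id": list(grouped.groups),
                "medium": medium,
                "unique_peptides": grouped["peptide_norm"].nunique().to_numpy(),
                "pmss": grouped["score"].sum().to_numpy(float),
            }
        )
        proteins["accepted"] = proteins["unique_peptides"] >= min_unique_peptides
        proteins = proteins.sort_values("protein_id", ignore_index=True)

    catalog = SecretomeCatalog(
        medium=medium,
        proteins=proteins,
        fdr_level=fdr_level,
        score_threshold=threshold,
        min_unique_peptides=min_unique_peptides,
        n_psms_read=len(psms),
    )
    logger.info(
        "medium=%s threshold=%s accepted=%d/%d proteins",
        medium, threshold, len(catalog.accepted_ids), len(proteins),
    )
    return catalog


def classify_presence(
    control: SecretomeCatalog, cm: SecretomeCatalog
) -> dict[str, str]:
    """Partition accepted proteins into unique_cm / shared / control_only.

    Diamonds, squares and (for panel factors added later) circles of the
    network figure convention map onto these classes by set membership only.
    """
    if control.fdr_level != cm.fdr_level:
        raise ValueError(
            "catalogs were built at different FDR levels "
            f"({control.fdr_level} vs {cm.fdr_level})"
        )
    control_ids, cm_ids = control.accepted_ids, cm.accepted_ids
    out: dict[str, str] = {}
    for pid in cm_ids - control_ids:
        out[pid] = "unique_cm"
    for pid in cm_ids & control_ids:
        out[pid] = "shared"
    for pid in control_ids - cm_ids:
        out[pid] = "control_only"
    return out
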