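"""Differential readouts: cytokine fold changes and 2^-ddCt regulation factors.

Multiplex cytokine concentrations are compared between conditions on the
concentration scale (log2fc = log2 of the ratio of arithmetic replicate
means).  qPCR readouts use the ddCt method: dCt normalizes a gene's mean Ct
to the housekeeping gene within a condition, ddCt compares conditions, and
the regulation factor is RF = 2^-ddCt, i.e. log2fc = -ddCt.  A measured
factor is called differential when |log2fc| meets a configurable threshold,
optionally AND-combined with a Welch-test p-value cut; the network stage
consumes the resulting set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeRecord",
    "read_cytokine_table",
    "read_ct_table",
    "delta_delta_ct",
    "ct_fold_changes",
    "cytokine_fold_changes",
    "call_differential",
    "pool_features",
    "heatmap_matrix",
    "export_heatmap",
]

FOLD_CHANGE_COLUMNS = (
    "feature", "subtype", "assay", "comparison", "log2fc", "fold_change",
    "rf", "pvalue", "differential",
)


def read_cytokine_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"analyte", "subtype", "condition", "replicate", "concentration"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"cytokine table {path} lacks columns: {sorted(missing)}")
    if (df["concentration"] <= 0).any():
        raise ValueError("cytokine concentrations must be strictly positive")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "subtype", "condition", "replicate", "ct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"Ct table {path} lacks columns: {sorted(missing)}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("Ct values must be finite")
    return df


@dataclass
class FoldChangeRecord:
    """One feature x subtype comparison between two conditions."""

    feature: str
    subtype: str
    assay: str                      # "cytokine" | "pcr"
    comparison: tuple[str, str]     # (treated, control)
    log2fc: float
    pvalue: float = math.nan
    differential: bool = False

    @property
    def fold_change(self) -> float:
        return 2.0 ** self.log2fc

    @property
    def rf(self) -> float:
        """Regulation factor RF = 2^-ddCt; equals 2**log2fc since ddCt = -log2fc."""
        return 2.0 ** self.log2fc

    @property
    def ddct(self) -> float:
        return -self.log2fc


def _records_frame(records: list[FoldChangeRecord]) -> pd.DataFrame:
    rows = [
        (
            r.feature, r.subtype, r.assay, f"{r.comparison[0]} vs {r.comparison[1]}",
            r.log2fc, r.fold_change, r.rf, r.pvalue, r.differential,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=FOLD_CHANGE_COLUMNS)


# ---------------------------------------------------------------------------
# qPCR: ddCt
# ---------------------------------------------------------------------------

def delta_delta_ct(
    ct_table: pd.DataFrame,
    gene: str,
    housekeeping_gene: str,
    treated_condition: str,
    control_condition: str,
    subtype: str,
) -> FoldChangeRecord:
    """RF = 2^-ddCt for one gene/subtype between two conditions.

    dCt(condition) = mean Ct(gene) - mean Ct(housekeeping); ddCt =
    dCt(treated) - dCt(control).  A Welch test on per-replicate dCt values
    provides the optional p-value.
    """
    sub = ct_table.loc[ct_table["subtype"] == subtype]

    def mean_ct(g: str, condition: str) -> float:
        vals = sub.loc[(sub["gene"] == g) & (sub["condition"] == condition), "ct"]
        if vals.empty:
            kind = "housekeeping" if g == housekeeping_gene else "gene"
            raise ValueError(
                f"no Ct rows for {kind} {g!r} in condition {condition!r} "
                f"(subtype {subtype!r})"
            )
        return float(vals.mean())

    dct = {
        cond: mean_ct(gene, cond) - mean_ct(housekeeping_gene, cond)
        for cond in (treated_condition, control_condition)
    }
    ddct = dct[treated_condition] - dct[control_condition]

    # replicate-level dCt for the Welch test (replicates paired within condition)
    def replicate_dct(condition: str) -> np.ndarray:
        rows = sub.loc[sub["condition"] == condition]
        g = rows.loc[rows["gene"] == gene].set_index("replicate")["ct"]
        hk = rows.loc[rows["gene"] == housekeeping_gene].set_index("replicate")["ct"]
        common = g.index.intersection(hk.index)
        return (g.loc[common] - hk.loc[common]).to_numpy(float)

    a, b = replicate_dct(treated_condition), replicate_dct(control_condition)
    pvalue = math.nan
    if len(a) > 1 and len(b) > 1:
        pvalue = float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    return FoldChangeRecord(
        feature=gene,
        subtype=subtype,
        assay="pcr",
        comparison=(treated_condition, control_condition),
        log2fc=-ddct,
        pvalue=pvalue,
    )


def ct_fold_changes(
    ct_table: pd.DataFrame,
    housekeeping_gene: str,
    treated_condition: str,
    control_condition: str,
) -> pd.DataFrame:
    """ddCt regulation factors for every (gene, subtype) except housekeeping."""
    genes = sorted(set(ct_table["gene"]) - {housekeeping_gene})
    subtypes = sorted(ct_table["subtype"].unique())
    records = [
        delta_delta_ct(
            ct_table, gene, housekeeping_gene,
            treated_condition, control_condition, subtype,
        )
        for gene in genes
        for subtype in subtypes
    ]
    return _records_frame(records)


# ---------------------------------------------------------------------------
# Multiplex cytokines
# ---------------------------------------------------------------------------

def cytokine_fold_changes(
    panel: pd.DataFrame,
    treated_condition: str,
    control_condition: str,
) -> pd.DataFrame:
    """log2fc of mean concentration, treated over control, per analyte/subtype."""
    records = []
    for (analyte, subtype), cell in panel.groupby(["analyte", "subtype"], sort=True):
        by_cond = {
            cond: cell.loc[cell["condition"] == cond, "concentration"].to_numpy(float)
            for cond in (treated_condition, control_condition)
        }
        for cond, vals in by_cond.items():
            if vals.size == 0:
                raise ValueError(
                    f"analyte {analyte!r} (subtype {subtype!r}) has no rows in "
                    f"condition {cond!r}"
                )
        means = {c: v.mean() for c, v in by_cond.items()}
        if means[treated_condition] <= 0 or means[control_condition] <= 0:
            raise ValueError(
                f"non-positive mean concentration for {analyte!r}/{subtype!r}"
            )
        log2fc = math.log2(means[treated_condition] / means[control_condition])
        pvalue = math.nan
        a, b = by_cond[treated_condition], by_cond[control_condition]
        if a.size > 1 and b.size > 1:
            # Welch on the log scale, matching the multiplicative noise model
            pvalue = float(
                stats.ttest_ind(np.log(a), np.log(b), equal_var=False).pvalue
            )
        records.append(
            FoldChangeRecord(
                feature=str(analyte),
                subtype=str(subtype),
                assay="cytokine",
                comparison=(treated_condition, control_condition),
                log2fc=log2fc,
                pvalue=pvalue,
            )
        )
    return _records_frame(records)


# ---------------------------------------------------------------------------
# Differential calls
# ---------------------------------------------------------------------------

def call_differential(
    records: pd.DataFrame,
    log2fc_threshold: float = 1.0,
    p_threshold: float | None = None,
) -> tuple[set[tuple[str, str]], pd.DataFrame]:
    """(feature, subtype) pairs with |log2fc| >= threshold (boundary inclusive).

    When ``p_threshold`` is given, the Welch p-value must also pass
    (AND-filter); rows with no p-value fail it.  Returns the set and a copy
    of the table with the ``differential`` flag updated.
    """
    if log2fc_threshold <= 0:
        raise ValueError("log2fc_threshold must be positive")
    out = records.copy()
    flag = out["log2fc"].abs() >= log2fc_threshold
    if p_threshold is not None:
        flag &= out["pvalue"] <= p_threshold
    out["differential"] = flag.fillna(False)
    selected = {
        (str(f), str(s))
        for f, s in out.loc[out["differential"], ["feature", "subtype"]].itertuples(
            index=False
        )
    }
    return selected, out


def pool_features(differential: set[tuple[str, str]]) -> set[str]:
    """Collapse (feature, subtype) calls to features, pooling across subtypes."""
    return {feature for feature, _ in differential}


# ---------------------------------------------------------------------------
# Heatmap export
# ---------------------------------------------------------------------------

def heatmap_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Analytes x subtypes matrix of log2fc, alphabetical both ways; NaN = missing."""
    mat = records.pivot_table(
        index="feature", columns="subtype", values="log2fc", aggfunc="first",
        dropna=False,
    )
    return mat.sort_index(axis=0).sort_index(axis=1)


def export_heatmap(
    matrix: pd.DataFrame,
    tsv_path: str | Path,
    png_path: str | Path | None = None,
) -> None:
    """Write the log2fc matrix as TSV and optionally render a PNG."""
    matrix.to_csv(tsv_path, sep="\t", na_rep="NA")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.5 * matrix.shape[1], 1 + 0.22 * matrix.shape[0])
        )
        vmax = float(np.nanmax(np.abs(matrix.to_numpy()))) if matrix.size else 1.0
        im = ax.imshow(
            matrix.to_numpy(float), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
            aspect="auto",
        )
        ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45)
        ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="log2 fold change")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
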