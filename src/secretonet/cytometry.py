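"""Threshold gating of flow-cytometry event tables.

Events are first viability-gated (7-AAD below threshold), then restricted to
CD68-positive cells (the general macrophage marker), and finally assigned to
exactly one of the eight CD163+/-, CD206+/-, CD80+/- marker combinations by
per-channel threshold comparison.  Rectangular fixed-threshold gating is
deliberate: no clustering, no hierarchy — thresholds are configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic import COMBO_LABELS

__all__ = [
    "GateConfig",
    "PopulationStats",
    "read_event_table",
    "apply_viability_gate",
    "filter_cd68_positive",
    "classify_combos",
    "gate_and_classify",
    "compare_populations",
]

logger = logging.getLogger(__name__)

MARKER_CHANNELS = ("CD68", "CD80", "CD163", "CD206")
VIABILITY_CHANNEL = "7AAD"


@dataclass(frozen=True)
class GateConfig:
    """Per-channel positivity thresholds in the same units as the event table."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "CD68": 1000.0, "CD80": 1000.0, "CD163": 1000.0, "CD206": 1000.0,
            VIABILITY_CHANNEL: 1000.0,
        }
    )
    viability_channel: str = VIABILITY_CHANNEL
    min_events: int = 10_000

    def __post_init__(self) -> None:
        for channel, t in self.thresholds.items():
            if t <= 0:
                raise ValueError(f"threshold for {channel} must be positive")
        if self.viability_channel not in self.thresholds:
            raise ValueError(
                f"no threshold configured for viability channel "
                f"{self.viability_channel!r}"
            )


@dataclass
class PopulationStats:
    """Counts and percentages of the eight combos among viable CD68+ events."""

    counts: dict[str, int]
    total: int
    gate: GateConfig

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {combo: 0.0 for combo in self.counts}
        return {c: 100.0 * n / self.total for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "combo": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [pct[c] for c in self.counts],
            }
        )


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = (set(MARKER_CHANNELS) | {VIABILITY_CHANNEL}) - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} lacks channels: {sorted(missing)}")
    channels = list(MARKER_CHANNELS) + [VIABILITY_CHANNEL]
    if (df[channels] < 0).any().any():
        raise ValueError("fluorescence intensities must be non-negative")
    return df


def apply_viability_gate(events: pd.DataFrame, gate: GateConfig) -> pd.DataFrame:
    """Retain events whose viability-dye intensity is below threshold."""
    channel = gate.viability_channel
    if channel not in events.columns:
        raise ValueError(f"event table lacks viability channel {channel!r}")
    viable = events.loc[events[channel] < gate.thresholds[channel]]
    if len(viable) < gate.min_events:
        logger.warning(
            "only %d viable events (below min_events=%d)", len(viable), gate.min_events
        )
    return viable


def filter_cd68_positive(events: pd.DataFrame, gate: GateConfig) -> pd.DataFrame:
    """Keep CD68-positive events (general macrophage marker pre-filter)."""
    if "CD68" not in events.columns:
        raise ValueError("event table lacks channel 'CD68'")
    return events.loc[events["CD68"] >= gate.thresholds["CD68"]]


def classify_combos(events: pd.DataFrame, gate: GateConfig) -> PopulationStats:
    """Assign each event to exactly one CD163/CD206/CD80 combo (>= t is positive).

    Expects events already viability-gated and CD68-filtered; the eight combos
    partition the events, so percentages sum to 100 whenever any event is
    classified.
    """
    for channel in ("CD163", "CD206", "CD80"):
        if channel not in events.columns:
            raise ValueError(f"event table lacks channel {channel!r}")
    sign = {
        channel: events[channel] >= gate.thresholds[channel]
        for channel in ("CD163", "CD206", "CD80")
    }
    counts = {}
    for combo in COMBO_LABELS:
        mask = pd.Series(True, index=events.index)
        for part in combo.split("/"):
            channel, s = part[:-1], part[-1]
            mask &= sign[channel] if s == "+" else ~sign[channel]
        counts[combo] = int(mask.sum())
    return PopulationStats(counts=counts, total=len(events), gate=gate)


def gate_and_classify(events: pd.DataFrame, gate: GateConfig) -> PopulationStats:
    """Full readout: viability gate, CD68 pre-filter, combo classification."""
    return classify_combos(
        filter_cd68_positive(apply_viability_gate(events, gate), gate), gate
    )


def compare_populations(
    stats_a: PopulationStats, stats_b: PopulationStats
) -> pd.DataFrame:
    """Per-combo percentage differences (a minus b); requires identical gates."""
    if stats_a.gate != stats_b.gate:
        raise ValueError("population stats come from different gate configurations")
    pa, pb = stats_a.percentages, stats_b.percentages
    return pd.DataFrame(
        {
            "combo": list(COMBO_LABELS),
            "percent_a": [pa[c] for c in COMBO_LABELS],
            "percent_b": [pb[c] for c in COMBO_LABELS],
            "difference": [pa[c] - pb[c] for c in COMBO_LABELS],
        }
    )
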