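"""Figure rendering: heterozygosity heatmaps, subset boxplots, coverage
tracks and marker ideograms."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from .coverage_sexchrom import CoverageBandProfile
from .het_windows import WindowTrack
from .str_localization import MarkerCall

__all__ = [
    "PlotSpec",
    "render",
    "bin_assign",
    "het_heatmap",
    "summary_boxplot",
    "coverage_track",
    "marker_map",
    "DEFAULT_HET_BREAKS",
]

# density breakpoints in SNPs/kbp; values at a threshold land in the upper bin
DEFAULT_HET_BREAKS = (0.1, 0.75)

_BAND_COLORS = {"half": "#1f3d7a", "full": "#20b2aa", "other": "#d3d3d3"}


@dataclass(frozen=True)
class PlotSpec:
    kind: str  # het_heatmap | summary_boxplot | coverage_track | marker_map
    out_path: str
    thresholds: tuple[float, ...] = DEFAULT_HET_BREAKS
    image_format: str | None = None  # inferred from out_path when None

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")


def bin_assign(value: float, thresholds: Sequence[float]) -> int:
    """Half-open left-closed bins; a value at a threshold goes to the upper bin."""
    return int(np.searchsorted(np.asarray(thresholds), value, side="right"))


def _ordered_scaffolds(values: Mapping[str, np.ndarray], window_size: int) -> list[str]:
    return sorted(values, key=lambda s: -len(values[s]) * window_size)


def het_heatmap(
    track: WindowTrack,
    out_path: str | Path,
    thresholds: Sequence[float] = DEFAULT_HET_BREAKS,
) -> None:
    """One horizontal bar per scaffold (longest first), windows colored by
    density bin."""
    if not track.values:
        raise ValueError("empty window track: nothing to draw")
    colors = plt.get_cmap("viridis")(np.linspace(0, 1, len(thresholds) + 1))
    order = _ordered_scaffolds(track.values, track.window_size)
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(order) + 1))
    for row, scaffold in enumerate(order):
        vals = track.values[scaffold]
        bins = np.searchsorted(np.asarray(thresholds), vals, side="right")
        for i, b in enumerate(bins):
            ax.add_patch(
                Rectangle(
                    (i * track.window_size, row), track.window_size, 0.8,
                    facecolor=colors[b], edgecolor="none",
                )
            )
    ax.set_yticks([r + 0.4 for r in range(len(order))])
    ax.set_yticklabels(order)
    ax.set_xlim(0, max(len(track.values[s]) for s in order) * track.window_size)
    ax.set_ylim(-0.2, len(order))
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def summary_boxplot(
    subsets: Mapping[str, np.ndarray],
    out_path: str | Path,
    clip_above: float | None = None,
) -> None:
    """Boxplot of window subsets; outliers above ``clip_above`` are not shown."""
    if not subsets:
        raise ValueError("no subsets to draw")
    labels = list(subsets)
    data = [np.asarray(subsets[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.5 * len(labels) + 1, 4))
    ax.boxplot(data, tick_labels=labels)
    if clip_above is not None:
        top = max(
            (float(np.max(d[d <= clip_above])) for d in data if np.any(d <= clip_above)),
            default=clip_above,
        )
        ax.set_ylim(top=max(clip_above, top) * 1.05)
    ax.set_ylabel("het SNPs / kbp")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def coverage_track(
    profile: CoverageBandProfile,
    out_path: str | Path,
) -> None:
    """Per-scaffold bars with windows colored by half/full/other band."""
    if not profile.medians:
        raise ValueError("empty coverage profile: nothing to draw")
    order = _ordered_scaffolds(profile.medians, profile.window_size)
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(order) + 1))
    for row, scaffold in enumerate(order):
        bands = profile.bands[scaffold]
        for i, band in enumerate(bands):
            ax.add_patch(
                Rectangle(
                    (i * profile.window_size, row), profile.window_size, 0.8,
                    facecolor=_BAND_COLORS[str(band)], edgecolor="none",
                )
            )
    ax.set_yticks([r + 0.4 for r in range(len(order))])
    ax.set_yticklabels(order)
    ax.set_xlim(0, max(profile.medians[s].size for s in order) * profile.window_size)
    ax.set_ylim(-0.2, len(order))
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def marker_map(
    calls: Sequence[MarkerCall],
    scaffold_lengths: Mapping[str, int],
    n_chromosomes: int,
    out_path: str | Path,
) -> None:
    """Ideogram: C-scaffold bars with localized markers as dots; scaffolds
    without markers are drawn light grey."""
    if not scaffold_lengths:
        raise ValueError("no scaffolds to draw")
    order = sorted(scaffold_lengths, key=lambda s: -scaffold_lengths[s])[:n_chromosomes]
    localized = [
        c for c in calls if c.category == "L" and c.chosen is not None
    ]
    labeled = {c.chosen.scaffold_id for c in localized}
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(order) + 1))
    for row, scaffold in enumerate(order):
        color = "#4c72b0" if scaffold in labeled else "#d3d3d3"
        ax.add_patch(
            Rectangle(
                (0, row), scaffold_lengths[scaffold], 0.6,
                facecolor=color, edgecolor="black", linewidth=0.5,
            )
        )
    for call in localized:
        if call.chosen.scaffold_id in order:
            row = order.index(call.chosen.scaffold_id)
            ax.plot(call.chosen.start, row + 0.3, "o", color="#c44e52", markersize=5)
            ax.annotate(
                call.marker_id, (call.chosen.start, row + 0.3),
                textcoords="offset points", xytext=(0, 6), fontsize=6,
            )
    ax.set_yticks([r + 0.3 for r in range(len(order))])
    ax.set_yticklabels(order)
    ax.set_xlim(0, max(scaffold_lengths[s] for s in order) * 1.02)
    ax.set_ylim(-0.2, len(order))
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def render(spec: PlotSpec, data) -> str:
    """Dispatch on :class:`PlotSpec` kind; returns the output path."""
    if spec.kind == "het_heatmap":
        het_heatmap(data, spec.out_path, spec.thresholds)
    elif spec.kind == "summary_boxplot":
        summary_boxplot(data, spec.out_path)
    elif spec.kind == "coverage_track":
        coverage_track(data, spec.out_path)
    elif spec.kind == "marker_map":
        calls, lengths, n_chromosomes = data
        marker_map(calls, lengths, n_chromosomes, spec.out_path)
    else:
        raise ValueError(f"unknown figure kind {spec.kind!r}")
    return spec.out_path
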