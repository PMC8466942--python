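"""Windowed heterozygous-SNP densities (SNPs per kbp).

Counts het SNPs in non-overlapping windows anchored at each scaffold
start; trailing partial windows are discarded, and window values are
scaled by the nominal window size regardless of gap content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .assembly_metrics import GenomeAssembly

__all__ = ["WindowTrack", "TrackSummary", "het_density", "summarize", "window_count"]

log = logging.getLogger(__name__)


@dataclass
class WindowTrack:
    """Per-scaffold fixed-width window values in SNPs per kbp."""

    window_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def starts(self, scaffold: str) -> np.ndarray:
        return np.arange(len(self.values[scaffold]), dtype=np.int64) * self.window_size

    @property
    def n_windows(self) -> int:
        return sum(len(v) for v in self.values.values())

    def pooled(self) -> np.ndarray:
        """All window values concatenated across scaffolds."""
        if not self.values:
            return np.empty(0)
        return np.concatenate([self.values[s] for s in self.values])

    def to_rows(self) -> Iterable[tuple[str, int, int, float]]:
        for scaffold, vals in self.values.items():
            for i, v in enumerate(vals):
                start = i * self.window_size
                yield scaffold, start, start + self.window_size, float(v)


@dataclass(frozen=True)
class TrackSummary:
    n_windows: int
    median: float | None
    mean: float | None
    total_het_snps: int


def _scaffold_lengths(assembly: GenomeAssembly | Mapping[str, int]) -> dict[str, int]:
    if isinstance(assembly, GenomeAssembly):
        return assembly.lengths
    return dict(assembly)


def window_count(assembly: GenomeAssembly | Mapping[str, int], window_size: int) -> int:
    """Complete non-overlapping windows tiling an assembly."""
    return sum(n // window_size for n in _scaffold_lengths(assembly).values())


def het_density(
    snp_positions: Mapping[str, Iterable[int]],
    assembly: GenomeAssembly | Mapping[str, int],
    window_size: int,
) -> WindowTrack:
    """Heterozygous-SNP density track.

    ``snp_positions`` maps scaffold id to 1-based het-SNP positions.  A
    window's value is its SNP count divided by (window_size / 1000).
    """
    if window_size < 1000:
        raise ValueError("window_size must be >= 1 kbp")
    lengths = _scaffold_lengths(assembly)
    unknown = set(snp_positions) - set(lengths)
    if unknown:
        raise ValueError(f"SNPs on scaffolds absent from assembly: {sorted(unknown)}")
    scale = window_size / 1000.0
    track = WindowTrack(window_size=window_size)
    for scaffold, length in lengths.items():
        n_win = length // window_size
        counts = np.zeros(n_win, dtype=np.float64)
        positions = np.asarray(list(snp_positions.get(scaffold, ())), dtype=np.int64)
        if positions.size:
            if positions.min() < 1 or positions.max() > length:
                raise ValueError(f"SNP position out of bounds on {scaffold}")
            idx = (positions - 1) // window_size
            idx = idx[idx < n_win]  # trailing partial window discarded
            np.add.at(counts, idx, 1.0)
        track.values[scaffold] = counts / scale
    return track


def summarize(track: WindowTrack) -> TrackSummary:
    """Pooled window count, median and mean plus total het SNPs in windows."""
    pooled = track.pooled()
    total = int(round(float(pooled.sum()) * track.window_size / 1000.0))
    if pooled.size == 0:
        log.warning("no complete windows at window size %d", track.window_size)
        return TrackSummary(n_windows=0, median=None, mean=None, total_het_snps=0)
    return TrackSummary(
        n_windows=int(pooled.size),
        median=float(np.median(pooled)),
        mean=float(np.mean(pooled)),
        total_het_snps=total,
    )
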