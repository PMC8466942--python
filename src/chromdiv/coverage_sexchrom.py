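"""X-chromosome identification and pseudoautosomal-region detection from depth.

In a male sample the X body is covered at ~0.5x of the genome median while
the PAR stays at ~1x.  The PAR caller works on 10-kbp window medians of
the X scaffold in three stages: threshold at 70% of the genome median and
merge adjacent qualifying windows, retain merged runs >= 100 kbp, then
bridge retained runs across gaps whose pooled depth median also clears
the 70% threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .depth import DepthTrack

__all__ = [
    "CoverageBandProfile",
    "ParCall",
    "window_median_depth",
    "identify_x",
    "detect_par",
    "HALF_BAND",
    "FULL_BAND",
]

log = logging.getLogger(__name__)

HALF_BAND = (0.25, 0.75)  # [lo, hi) as fraction of genome median
FULL_BAND = (0.75, 1.25)  # [lo, hi]; 0.75 ties go to "full"

PAR_WINDOW = 10_000
SCAN_WINDOW = 1_000_000
PAR_DEPTH_FRACTION = 0.7
PAR_MIN_RUN = 100_000


@dataclass
class CoverageBandProfile:
    """Per-scaffold window median depths with half/full/other band labels."""

    window_size: int
    genome_median: float
    medians: dict[str, np.ndarray] = field(default_factory=dict)
    bands: dict[str, np.ndarray] = field(default_factory=dict)  # 'half'|'full'|'other'

    def half_fraction(self, scaffold: str) -> float:
        bands = self.bands[scaffold]
        return float(np.mean(bands == "half")) if bands.size else 0.0


@dataclass
class ParCall:
    x_scaffold: str
    par_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def par_length(self) -> int:
        return sum(end - start for start, end in self.par_intervals)


def _window_medians(arr: np.ndarray, window_size: int) -> np.ndarray:
    """Median per stacking window; the trailing partial window, if any,
    uses its actual bases."""
    n = arr.size
    n_full = n // window_size
    out = []
    if n_full:
        trimmed = arr[: n_full * window_size].reshape(n_full, window_size)
        out.append(np.median(trimmed, axis=1))
    if n % window_size:
        out.append(np.array([np.median(arr[n_full * window_size:])]))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def classify_band(ratio: float) -> str:
    if HALF_BAND[0] <= ratio < HALF_BAND[1]:
        return "half"
    if FULL_BAND[0] <= ratio <= FULL_BAND[1]:
        return "full"
    return "other"


def window_median_depth(
    track: DepthTrack,
    window_size: int = SCAN_WINDOW,
    genome_median: float | None = None,
) -> CoverageBandProfile:
    """Window median depths and coverage-band labels for every scaffold."""
    if genome_median is None:
        genome_median = track.genome_median()
    if genome_median <= 0:
        raise ValueError("genome median depth must be positive")
    profile = CoverageBandProfile(window_size=window_size, genome_median=genome_median)
    for scaffold in track.scaffolds():
        arr = track.expand(scaffold)
        if arr.size == 0:
            log.warning("skipping empty scaffold %s", scaffold)
            continue
        med = _window_medians(arr, window_size)
        profile.medians[scaffold] = med
        ratios = med / genome_median
        profile.bands[scaffold] = np.array([classify_band(r) for r in ratios])
    return profile


def identify_x(
    profile: CoverageBandProfile,
    sex: str = "male",
    n_largest: int | None = None,
    min_half_fraction: float = 0.5,
) -> str:
    """Scaffold with the greatest fraction of half-coverage windows.

    Only works for male samples (female X depth matches autosomes).  When
    ``n_largest`` is given, only the that many longest scaffolds
    (C-scaffold candidates) are considered.  The winning fraction must
    exceed ``min_half_fraction``.
    """
    if sex != "male":
        raise ValueError(
            "X identification from depth requires a male sample; "
            "female samples show no depth contrast on X"
        )
    lengths = {
        s: int(profile.medians[s].size) * profile.window_size for s in profile.medians
    }
    candidates = sorted(lengths, key=lambda s: -lengths[s])
    if n_largest is not None:
        candidates = candidates[:n_largest]
    if not candidates:
        raise ValueError("no scaffolds in coverage profile")
    best = max(candidates, key=profile.half_fraction)
    if profile.half_fraction(best) <= min_half_fraction:
        raise ValueError(
            "X not identifiable: no scaffold exceeds "
            f"{min_half_fraction:.0%} half-coverage windows"
        )
    return best


def detect_par(
    track: DepthTrack,
    x_scaffold: str,
    genome_median: float | None = None,
    window_size: int = PAR_WINDOW,
    depth_fraction: float = PAR_DEPTH_FRACTION,
    min_run: int = PAR_MIN_RUN,
) -> ParCall:
    """Detect pseudoautosomal interval(s) on the X scaffold.

    Stage 1: mark 10-kbp windows with median depth >= depth_fraction x
    genome median and merge adjacent marked windows into runs.
    Stage 2: retain runs spanning >= 100 kbp.
    Stage 3: merge neighbouring retained runs when the pooled per-base
    depth median of the intervening gap also clears the threshold.
    """
    if genome_median is None:
        genome_median = track.genome_median()
    if genome_median <= 0:
        raise ValueError("genome median depth must be positive")
    threshold = depth_fraction * genome_median
    arr = track.expand(x_scaffold)
    if arr.size == 0:
        raise ValueError(f"empty X scaffold {x_scaffold!r}")
    medians = _window_medians(arr, window_size)
    n = arr.size

    def window_span(i: int) -> tuple[int, int]:
        return i * window_size, min((i + 1) * window_size, n)

    # stage 1: adjacent qualifying windows -> runs
    marked = medians >= threshold
    runs: list[tuple[int, int]] = []
    i = 0
    while i < marked.size:
        if marked[i]:
            j = i
            while j + 1 < marked.size and marked[j + 1]:
                j += 1
            runs.append((window_span(i)[0], window_span(j)[1]))
            i = j + 1
        else:
            i += 1

    # stage 2: length filter on merged runs
    retained = [(s, e) for s, e in runs if e - s >= min_run]
    if not retained:
        log.warning("no PAR-like run >= %d bp on %s", min_run, x_scaffold)
        return ParCall(x_scaffold=x_scaffold)

    # stage 3: bridge across qualifying gaps
    merged: list[tuple[int, int]] = [retained[0]]
    for start, end in retained[1:]:
        prev_start, prev_end = merged[-1]
        gap = arr[prev_end:start]
        if gap.size and float(np.median(gap)) >= threshold:
            merged[-1] = (prev_start, end)
        else:
            merged.append((start, end))
    return ParCall(x_scaffold=x_scaffold, par_intervals=merged)
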