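"""Run-length per-base depth tracks backed by bedGraph files.

Depth is kept run-length encoded; a per-base array is materialized for at
most one scaffold at a time.  The whole-genome median is computed exactly
from the runs without expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["DepthTrack", "read_bedgraph", "write_bedgraph"]


@dataclass
class DepthTrack:
    """Per-scaffold depth as sorted, contiguous (start, end, depth) runs.

    Coordinates are 0-based half-open.  Bases not covered by any run are
    treated as depth 0 up to the scaffold length when one is declared.
    Scaffolds may alternatively be backed by dense per-base arrays
    (in-memory simulation output); the two storage forms never mix for
    one scaffold.
    """

    runs: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "DepthTrack":
        out = {}
        for s, a in arrays.items():
            a = np.asarray(a)
            if not np.issubdtype(a.dtype, np.number):
                a = a.astype(np.float64)
            out[s] = a
        return cls(arrays=out)

    def add_run(self, scaffold: str, start: int, end: int, depth: float) -> None:
        if end <= start:
            raise ValueError(f"empty run {scaffold}:{start}-{end}")
        if scaffold in self.arrays:
            raise ValueError(f"scaffold {scaffold} is array-backed")
        self.runs.setdefault(scaffold, []).append((start, end, float(depth)))

    def scaffolds(self) -> list[str]:
        return list(self.runs) + [s for s in self.arrays if s not in self.runs]

    def length(self, scaffold: str) -> int:
        if scaffold in self.scaffold_lengths:
            return self.scaffold_lengths[scaffold]
        if scaffold in self.arrays:
            return int(self.arrays[scaffold].size)
        return max(end for _, end, _ in self.runs[scaffold])

    def expand(self, scaffold: str) -> np.ndarray:
        """Materialize one scaffold as a per-base float array."""
        if scaffold in self.arrays:
            return self.arrays[scaffold]
        n = self.length(scaffold)
        arr = np.zeros(n, dtype=np.float64)
        for start, end, depth in self.runs.get(scaffold, []):
            arr[start:end] = depth
        return arr

    def iter_values(self) -> Iterator[tuple[float, int]]:
        """Yield (depth, n_bases) pairs over the whole genome, zeros included."""
        for scaffold in self.arrays:
            arr = self.arrays[scaffold]
            if np.issubdtype(arr.dtype, np.integer) and arr.size and arr.min() >= 0:
                counts = np.bincount(arr)  # avoids a full sort on big tracks
                for v in np.flatnonzero(counts):
                    yield float(v), int(counts[v])
                if counts.size and counts[0]:
                    yield 0.0, int(counts[0])
            else:
                values, counts = np.unique(arr, return_counts=True)
                for v, c in zip(values, counts):
                    yield float(v), int(c)
        for scaffold in self.runs:
            covered = 0
            for start, end, depth in sorted(self.runs[scaffold]):
                if start > covered:
                    yield 0.0, start - covered
                yield depth, end - start
                covered = max(covered, end)
            n = self.length(scaffold)
            if n > covered:
                yield 0.0, n - covered

    def genome_median(self) -> float:
        """Exact median of per-base depth over all scaffolds concatenated."""
        pairs = sorted(self.iter_values())
        total = sum(w for _, w in pairs)
        if total == 0:
            raise ValueError("empty depth track")
        # positions of the middle base(s), 0-based
        lo_idx = (total - 1) // 2
        hi_idx = total // 2
        acc = 0
        lo = hi = None
        for value, weight in pairs:
            acc += weight
            if lo is None and acc > lo_idx:
                lo = value
            if acc > hi_idx:
                hi = value
                break
        assert lo is not None and hi is not None
        return (lo + hi) / 2.0


def read_bedgraph(path: str | Path, scaffold_lengths: dict[str, int] | None = None) -> DepthTrack:
    """Read a 4-column bedGraph (scaffold, start, end, depth) into a track."""
    track = DepthTrack(scaffold_lengths=dict(scaffold_lengths or {}))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            scaffold, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            track.add_run(scaffold, start, end, depth)
    return track


def _rle(arr: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Run-length encode a dense array into (start, end, value) runs."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), float(arr[s])


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold in track.scaffolds():
            if scaffold in track.arrays:
                runs = _rle(track.arrays[scaffold])
            else:
                runs = iter(sorted(track.runs[scaffold]))
            for start, end, depth in runs:
                d = int(depth) if float(depth).is_integer() else depth
                fh.write(f"{scaffold}\t{start}\t{end}\t{d}\n")
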