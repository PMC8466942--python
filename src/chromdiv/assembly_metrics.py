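"""Assembly summary statistics and draft vs chromosome-level comparison.

Works on plain multi-record FASTA files.  Only ``N``/``n`` counts as gap
sequence; other ambiguity codes are treated as resolved bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GenomeAssembly",
    "AssemblyMetrics",
    "AssemblyComparison",
    "FastaParseError",
    "read_fasta",
    "compute_metrics",
    "compare_assemblies",
    "display_fold",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass
class GenomeAssembly:
    """Ordered named scaffolds with uppercased sequence."""

    scaffolds: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, seq in self.scaffolds:
            if name in seen:
                raise ValueError(f"duplicate scaffold id: {name!r}")
            seen.add(name)
            if len(seq) < 1:
                raise ValueError(f"empty scaffold: {name!r}")

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.scaffolds]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds}

    def sequence(self, scaffold_id: str) -> str:
        for name, seq in self.scaffolds:
            if name == scaffold_id:
                return seq
        raise KeyError(scaffold_id)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __iter__(self):
        return iter(self.scaffolds)


@dataclass(frozen=True)
class AssemblyMetrics:
    total_length: int
    gap_length: int
    scaffold_n50: int
    scaffold_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.gap_length <= self.total_length:
            raise ValueError("gap_length must be within [0, total_length]")


@dataclass(frozen=True)
class AssemblyComparison:
    """Chromosome-level over draft: N50 fold change and signed gap change."""

    n50_fold: float
    n50_fold_display: float | int
    dn_abs_bp: int
    dn_pct: float | None  # None when draft has no gaps

    @property
    def dn_abs_mbp(self) -> float:
        return self.dn_abs_bp / 1e6


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Parse a multi-record FASTA into a :class:`GenomeAssembly`.

    Sequences are uppercased, record order is preserved.  Headers are
    truncated at the first whitespace.
    """
    scaffolds: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"empty record {name!r} before line {lineno}")
        scaffolds.append((name, seq.upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()
                if not header:
                    raise FastaParseError(f"empty FASTA header at line {lineno}")
                name = header[0]
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"sequence before any header at line {lineno}"
                    )
                chunks.append(line)
    flush(lineno=-1)
    if not scaffolds:
        raise FastaParseError(f"no FASTA records in {path}")
    try:
        return GenomeAssembly(scaffolds)
    except ValueError as exc:
        raise FastaParseError(str(exc)) from exc


def n50(lengths: Iterable[int]) -> int:
    """Length L such that scaffolds of length >= L cover >= 50% of the total.

    When the cumulative sum hits exactly 50%, that scaffold's length is
    returned (standard assembly-stats convention).
    """
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("empty length list")
    half = sum(ls) / 2
    acc = 0
    for length in ls:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def compute_metrics(assembly: GenomeAssembly) -> AssemblyMetrics:
    """Total length, N-gap length, scaffold N50 and count for an assembly."""
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    lengths = [len(seq) for _, seq in assembly]
    gaps = sum(seq.count("N") for _, seq in assembly)
    return AssemblyMetrics(
        total_length=sum(lengths),
        gap_length=gaps,
        scaffold_n50=n50(lengths),
        scaffold_count=len(lengths),
    )


def display_fold(fold: float) -> float | int:
    """Paper-style display of an N50 fold improvement.

    Integer part for folds >= 10, round-half-even to one decimal below 10.
    """
    if fold >= 10:
        return int(fold)
    return round(fold, 1)


def compare_assemblies(
    draft: AssemblyMetrics, chrom: AssemblyMetrics
) -> AssemblyComparison:
    """Compare a draft against the chromosome-level assembly of one species."""
    if draft.scaffold_n50 <= 0:
        raise ValueError("draft N50 must be positive")
    fold = chrom.scaffold_n50 / draft.scaffold_n50
    dn_abs = chrom.gap_length - draft.gap_length
    dn_pct = 100.0 * dn_abs / draft.gap_length if draft.gap_length > 0 else None
    return AssemblyComparison(
        n50_fold=fold,
        n50_fold_display=display_fold(fold),
        dn_abs_bp=dn_abs,
        dn_pct=dn_pct,
    )


def metrics_row(species: str, level: str, m: AssemblyMetrics) -> Mapping[str, object]:
    return {
        "species": species,
        "level": level,
        "length_bp": m.total_length,
        "ns_bp": m.gap_length,
        "n50_bp": m.scaffold_n50,
        "scaffold_count": m.scaffold_count,
    }
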