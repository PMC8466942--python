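"""Variant quality filtering and coverage-band retention.

Implements the hard-threshold site filter (QUAL < 20, SP > 60, DP < 5,
GQ < 20 -> drop), the 50-250%-of-median coverage retention mask, and the
SNP/indel split.  Consumes single-sample VCF 4.x with DP, GQ and SP
FORMAT fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .depth import DepthTrack

__all__ = [
    "VariantRecord",
    "CoverageMask",
    "VcfStream",
    "read_vcf",
    "quality_filter",
    "build_coverage_mask",
    "apply_mask",
    "split_snp_indel",
    "is_heterozygous",
    "write_vcf",
]

log = logging.getLogger(__name__)

QUAL_MIN = 20.0
SP_MAX = 60.0
DP_MIN = 5.0
GQ_MIN = 20.0

COVERAGE_BAND = (0.5, 2.5)  # retention band as fraction of genome median, inclusive


@dataclass(frozen=True)
class VariantRecord:
    """One VCF line restricted to the fields the pipeline uses."""

    scaffold_id: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    qual: float
    sample_dp: float
    sample_gq: float
    sample_sp: float
    genotype: tuple[int, int]
    phased: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based")
        n_alleles = 1 + len(self.alt)
        for idx in self.genotype:
            if not 0 <= idx < n_alleles:
                raise ValueError(f"genotype index {idx} out of range")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alt)


@dataclass
class CoverageMask:
    """Per-scaffold sorted, non-overlapping half-open retained intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def contains(self, scaffold: str, pos0: int) -> bool:
        ivs = self.intervals.get(scaffold)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        # binary search for the interval that could contain pos0
        import bisect

        i = bisect.bisect_right(starts, pos0) - 1
        if i < 0:
            return False
        start, end = ivs[i]
        return start <= pos0 < end


class VcfStream:
    """Iterator over :class:`VariantRecord` with a skip tally.

    Records missing QUAL or any of the DP/GQ/SP FORMAT values are
    excluded with a warning and counted in :attr:`skipped`.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.skipped = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        with pysam.VariantFile(self.path) as vcf:
            samples = list(vcf.header.samples)
            if len(samples) != 1:
                raise ValueError(
                    f"expected single-sample VCF, found {len(samples)} samples"
                )
            for rec in vcf:
                parsed = self._parse(rec)
                if parsed is None:
                    self.skipped += 1
                else:
                    yield parsed

    def _parse(self, rec: "pysam.VariantRecord") -> VariantRecord | None:
        sample = rec.samples[0]
        dp = sample.get("DP")
        gq = sample.get("GQ")
        sp = sample.get("SP")
        gt = sample.get("GT")
        missing = [
            name
            for name, value in (("QUAL", rec.qual), ("DP", dp), ("GQ", gq), ("SP", sp))
            if value is None
        ]
        if missing or gt is None or any(a is None for a in gt):
            log.warning(
                "skipping %s:%s: missing %s",
                rec.chrom,
                rec.pos,
                ",".join(missing) or "GT",
            )
            return None
        return VariantRecord(
            scaffold_id=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=tuple(rec.alts or ()),
            qual=float(rec.qual),
            sample_dp=float(dp),
            sample_gq=float(gq),
            sample_sp=float(sp),
            genotype=(int(gt[0]), int(gt[1])),
            phased=bool(sample.phased),
        )


def read_vcf(path: str | Path) -> VcfStream:
    """Open a VCF for streaming; returns an iterable with a ``skipped`` tally."""
    return VcfStream(path)


def quality_filter(record: VariantRecord) -> bool:
    """True = keep.  Drop iff QUAL < 20 or SP > 60 or DP < 5 or GQ < 20."""
    return not (
        record.qual < QUAL_MIN
        or record.sample_sp > SP_MAX
        or record.sample_dp < DP_MIN
        or record.sample_gq < GQ_MIN
    )


def build_coverage_mask(depth: DepthTrack, genome_median: float | None = None) -> CoverageMask:
    """Maximal runs of bases with depth in [0.5, 2.5] x genome median.

    Both band edges are inclusive.  The median defaults to the track's own
    whole-genome median.
    """
    if genome_median is None:
        genome_median = depth.genome_median()
    if genome_median <= 0:
        raise ValueError("genome median depth must be positive")
    lo = COVERAGE_BAND[0] * genome_median
    hi = COVERAGE_BAND[1] * genome_median
    mask = CoverageMask()
    for scaffold in depth.scaffolds():
        arr = depth.expand(scaffold)
        ok = (arr >= lo) & (arr <= hi)
        mask.intervals[scaffold] = _bool_runs(ok)
    return mask


def _bool_runs(ok: np.ndarray) -> list[tuple[int, int]]:
    """Half-open intervals of True runs in a boolean array."""
    if ok.size == 0:
        return []
    padded = np.concatenate(([False], ok, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def apply_mask(
    records: Iterable[VariantRecord],
    mask: CoverageMask,
    dropped_counter: list[int] | None = None,
) -> Iterator[VariantRecord]:
    """Retain records whose 0-based position lies inside a mask interval.

    Records on scaffolds absent from the mask are dropped and counted.
    """
    dropped = 0
    for rec in records:
        if mask.contains(rec.scaffold_id, rec.pos - 1):
            yield rec
        else:
            dropped += 1
    if dropped_counter is not None:
        dropped_counter.append(dropped)


def split_snp_indel(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split into (snps, indels).

    SNP iff ref and every alt allele have length 1; mixed multi-allelic
    records go to the indel bucket.
    """
    snps: list[VariantRecord] = []
    indels: list[VariantRecord] = []
    for rec in records:
        (snps if rec.is_snp else indels).append(rec)
    return snps, indels


def is_heterozygous(record: VariantRecord) -> bool:
    """Two distinct alleles in the genotype (0/1, 1/2, ...)."""
    return record.genotype[0] != record.genotype[1]


def write_vcf(records: Iterable[VariantRecord], path: str | Path, template: str | Path) -> int:
    """Write records to ``path`` copying positions from the template VCF.

    The template is re-read and records matching (scaffold, pos, ref, alt)
    of the kept set are copied verbatim, preserving all annotation.
    Returns the number of records written.
    """
    keys = {(r.scaffold_id, r.pos, r.ref, r.alt) for r in records}
    written = 0
    with pysam.VariantFile(str(template)) as src:
        with open(path, "w") as out:
            out.write(str(src.header))
            for rec in src:
                key = (rec.chrom, rec.pos, rec.ref, tuple(rec.alts or ()))
                if key in keys:
                    out.write(str(rec))
                    written += 1
    return written
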