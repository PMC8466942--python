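"""In silico PCR of STR primer panels with mismatch scoring and
NA/D/L classification.

Primer sites are found by an end-to-end Hamming alignment (no indels) on
both strands, allowing up to four mismatches per primer.  IUPAC codes in
the primer match their expansion sets; an N in the genome matches
nothing.  Amplicons are products of two facing sites 50-1000 bp apart,
scored by MM = max(forward mismatches, reverse mismatches) and
TM = forward + reverse mismatches, ranked ascending by (MM, TM, length).

Classification: NA when a marker yields no product; L when the top
product is a two-primer (FR/RF) amplicon with MM <= 3 and is either the
only product (group 1) or separated from the runner-up by dMM >= 2 or
dTM >= 3 (group 2); D otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .assembly_metrics import GenomeAssembly

__all__ = [
    "PrimerPair",
    "PrimerSite",
    "Amplicon",
    "MarkerCall",
    "PanelSummary",
    "find_primer_sites",
    "pair_amplicons",
    "rank_amplicons",
    "classify_marker",
    "localize_marker",
    "localize_panel",
    "panel_report",
    "mean_overall_density",
    "mean_labeled_density",
    "read_panel",
    "revcomp",
    "MAX_MISMATCH",
]

MAX_MISMATCH = 4
MIN_AMPLICON = 50
MAX_AMPLICON = 1000
MM_ACCEPT = 3  # top amplicon MM score ceiling for category L
DELTA_MM = 2  # group-2 separation thresholds
DELTA_TM = 3

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)

# genome byte -> base bit; everything unrecognised (incl. N) matches nothing
_GENOME_LUT = np.zeros(256, dtype=np.uint8)
for _b, _bit in _BASE_BIT.items():
    _GENOME_LUT[ord(_b)] = _bit
    _GENOME_LUT[ord(_b.lower())] = _bit


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primer_masks(primer: str) -> np.ndarray:
    masks = np.empty(len(primer), dtype=np.uint8)
    for i, ch in enumerate(primer.upper()):
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in primer {primer!r}")
        masks[i] = sum(_BASE_BIT[b] for b in IUPAC[ch])
    return masks


def _encode(seq: str) -> np.ndarray:
    return _GENOME_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PrimerPair:
    marker_id: str
    forward: str
    reverse: str
    source_species: str = ""
    source_publication: str = ""

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError(f"primer shorter than 10 nt in {self.marker_id}")
            _primer_masks(p)  # validates alphabet


@dataclass(frozen=True)
class PrimerSite:
    """End-to-end primer alignment; start is the leftmost genome coordinate
    of the footprint on the forward strand, strand is where the primer's
    5'->3' sequence matches."""

    scaffold: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Amplicon:
    scaffold_id: str
    start: int
    end: int  # outermost footprint coordinates, half-open
    orientation: str  # FR | RF | FF | RR
    fwd_mismatches: int  # upstream-end primer mismatches
    rev_mismatches: int  # downstream-end primer mismatches

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mm_score(self) -> int:
        return max(self.fwd_mismatches, self.rev_mismatches)

    @property
    def tm_score(self) -> int:
        return self.fwd_mismatches + self.rev_mismatches

    @property
    def single_primer(self) -> bool:
        return self.orientation in ("FF", "RR")


@dataclass
class MarkerCall:
    marker_id: str
    category: str  # NA | D | L
    group: int | None  # 1 | 2 | None
    chosen: Amplicon | None
    all_amplicons: list[Amplicon] = field(default_factory=list)


@dataclass(frozen=True)
class PanelSummary:
    n_localized: int
    n_not_amplified: int
    n_declined: int
    n_chromosomes: int
    n_chrom_with_markers: int

    @property
    def n_chrom_without_markers(self) -> int:
        return self.n_chromosomes - self.n_chrom_with_markers

    @property
    def overall_density(self) -> float:
        """Localized markers per chromosome."""
        return self.n_localized / self.n_chromosomes

    @property
    def labeled_density(self) -> float:
        """Localized markers per chromosome that carries at least one."""
        if self.n_chrom_with_markers == 0:
            return 0.0
        return self.n_localized / self.n_chrom_with_markers


def _scan_strand(encoded: np.ndarray, masks: np.ndarray, max_mismatch: int) -> np.ndarray:
    """Mismatch counts of an end-to-end alignment at every start position."""
    m = len(masks)
    n = encoded.size
    if n < m:
        return np.empty(0, dtype=np.int16)
    width = n - m + 1
    mism = np.zeros(width, dtype=np.int16)
    for j in range(m):
        mism += (encoded[j : j + width] & masks[j]) == 0
    return mism


def find_primer_sites(
    assembly: GenomeAssembly,
    primer: str,
    max_mismatch: int = MAX_MISMATCH,
) -> list[PrimerSite]:
    """All positions on either strand where the primer aligns end-to-end
    with at most ``max_mismatch`` Hamming mismatches."""
    if not primer:
        raise ValueError("empty primer")
    fwd_masks = _primer_masks(primer)
    rev_masks = _primer_masks(revcomp(primer))
    m = len(primer)
    sites: list[PrimerSite] = []
    for scaffold, seq in assembly:
        enc = _encode(seq)
        for strand, masks in (("+", fwd_masks), ("-", rev_masks)):
            mism = _scan_strand(enc, masks, max_mismatch)
            for pos in np.flatnonzero(mism <= max_mismatch):
                sites.append(
                    PrimerSite(scaffold, int(pos), strand, int(mism[pos]), m)
                )
    return sites


def pair_amplicons(
    fwd_hits: Sequence[PrimerSite],
    rev_hits: Sequence[PrimerSite],
    min_len: int = MIN_AMPLICON,
    max_len: int = MAX_AMPLICON,
) -> list[Amplicon]:
    """Products of two facing sites with span in [min_len, max_len].

    The upstream member must match the + strand and the downstream one
    the - strand.  Same-primer (FF/RR) facing pairs are emitted too, but
    they can never be classified L.
    """
    combos = (
        ("FR", fwd_hits, rev_hits),
        ("RF", rev_hits, fwd_hits),
        ("FF", fwd_hits, fwd_hits),
        ("RR", rev_hits, rev_hits),
    )
    amplicons: list[Amplicon] = []
    for orientation, up_pool, down_pool in combos:
        ups = [h for h in up_pool if h.strand == "+"]
        downs = [h for h in down_pool if h.strand == "-"]
        for up in ups:
            for down in downs:
                if down.scaffold != up.scaffold or down.start < up.start:
                    continue
                span = down.end - up.start
                if min_len <= span <= max_len:
                    amplicons.append(
                        Amplicon(
                            scaffold_id=up.scaffold,
                            start=up.start,
                            end=down.end,
                            orientation=orientation,
                            fwd_mismatches=up.mismatches,
                            rev_mismatches=down.mismatches,
                        )
                    )
    return amplicons


def rank_amplicons(amplicons: Sequence[Amplicon]) -> list[Amplicon]:
    """Stable ascending sort by (MM score, TM score, length)."""
    return sorted(amplicons, key=lambda a: (a.mm_score, a.tm_score, a.length))


def classify_marker(marker: PrimerPair, amplicons: Sequence[Amplicon]) -> MarkerCall:
    """Apply the NA/D/L rules to one marker's amplicon list."""
    if not amplicons:
        return MarkerCall(marker.marker_id, "NA", None, None, [])
    ranked = rank_amplicons(amplicons)
    top = ranked[0]
    if top.orientation in ("FR", "RF") and top.mm_score <= MM_ACCEPT:
        if len(ranked) == 1:
            return MarkerCall(marker.marker_id, "L", 1, top, ranked)
        second = ranked[1]
        if (second.mm_score - top.mm_score >= DELTA_MM) or (
            second.tm_score - top.tm_score >= DELTA_TM
        ):
            return MarkerCall(marker.marker_id, "L", 2, top, ranked)
    return MarkerCall(marker.marker_id, "D", None, None, ranked)


def localize_marker(
    assembly: GenomeAssembly,
    marker: PrimerPair,
    max_mismatch: int = MAX_MISMATCH,
) -> MarkerCall:
    fwd_hits = find_primer_sites(assembly, marker.forward, max_mismatch)
    rev_hits = find_primer_sites(assembly, marker.reverse, max_mismatch)
    amplicons = pair_amplicons(fwd_hits, rev_hits)
    return classify_marker(marker, amplicons)


def localize_panel(
    assembly: GenomeAssembly,
    panel: Sequence[PrimerPair],
    max_mismatch: int = MAX_MISMATCH,
) -> list[MarkerCall]:
    seen = set()
    for marker in panel:
        if marker.marker_id in seen:
            raise ValueError(f"duplicate marker id {marker.marker_id!r}")
        seen.add(marker.marker_id)
    return [localize_marker(assembly, m, max_mismatch) for m in panel]


def panel_report(
    calls: Sequence[MarkerCall],
    assembly: GenomeAssembly,
    n_chromosomes: int,
) -> PanelSummary:
    """Per-assembly marker summary over the designated C-scaffolds
    (the ``n_chromosomes`` longest scaffolds)."""
    if n_chromosomes > len(assembly):
        raise ValueError(
            f"n_chromosomes={n_chromosomes} exceeds scaffold count {len(assembly)}"
        )
    lengths = assembly.lengths
    c_scaffolds = set(
        sorted(lengths, key=lambda s: -lengths[s])[:n_chromosomes]
    )
    labeled = {
        c.chosen.scaffold_id
        for c in calls
        if c.category == "L" and c.chosen is not None
        and c.chosen.scaffold_id in c_scaffolds
    }
    return PanelSummary(
        n_localized=sum(c.category == "L" for c in calls),
        n_not_amplified=sum(c.category == "NA" for c in calls),
        n_declined=sum(c.category == "D" for c in calls),
        n_chromosomes=n_chromosomes,
        n_chrom_with_markers=len(labeled),
    )


def mean_overall_density(summaries: Iterable[PanelSummary]) -> float:
    vals = [s.overall_density for s in summaries]
    return sum(vals) / len(vals)


def mean_labeled_density(summaries: Iterable[PanelSummary]) -> float:
    vals = [s.labeled_density for s in summaries]
    return sum(vals) / len(vals)


def read_panel(path: str | Path) -> list[PrimerPair]:
    """Read a primer panel TSV with columns marker_id, forward, reverse
    and optional source columns; a header line is detected and skipped."""
    panel: list[PrimerPair] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in ("marker_id", "marker", "id"):
                continue
            marker_id, forward, reverse = row[0], row[1], row[2]
            source_species = row[3] if len(row) > 3 else ""
            source_pub = row[4] if len(row) > 4 else ""
            panel.append(
                PrimerPair(marker_id, forward, reverse, source_species, source_pub)
            )
    return panel
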