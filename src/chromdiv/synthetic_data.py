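"""Seeded generators for synthetic genomes, variants, depth and primer panels.

The generated data carry the statistical structure the analysis assumes:
a multi-chromosome diploid genome with heterozygosity hot/cold spots and
an X chromosome with a terminal pseudoautosomal region; a fragmented
draft of the same sequence; single-sample VCF records whose QUAL/DP/GQ/SP
values span the filter thresholds at configured failure fractions; male
depth tracks at half coverage on the X body; and primer panels with
planted targets and decoys covering the whole NA/D/L classification
space.  All outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .assembly_metrics import GenomeAssembly, compute_metrics
from .depth import DepthTrack
from .str_localization import PrimerPair, revcomp

__all__ = [
    "RateProfile",
    "MarkerScenario",
    "SimulationConfig",
    "SimulatedGenome",
    "VariantTruth",
    "simulate_genome",
    "simulate_variants",
    "simulate_depth",
    "simulate_panel",
    "simulate_window_values",
    "write_vcf_text",
    "write_fasta",
    "write_panel_tsv",
    "DEFAULT_PANEL",
    "MARKER_SCENARIO_KINDS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MARKER_SCENARIO_KINDS = (
    "L1",        # exact unique target -> L group 1
    "L2_dMM",    # target + decoy separated by dMM >= 2 -> L group 2
    "L2_dTM",    # target + decoy separated by dTM >= 3 (dMM < 2) -> L group 2
    "D_close",   # target + decoy inside both separation bounds -> D
    "D_MM4",     # single amplicon with MM score 4 -> D
    "D_single",  # only a same-primer (FF) product -> D
    "NA",        # no binding sites planted -> NA
)

# (target fwd/rev mismatches, decoy fwd/rev mismatches or None)
_SCENARIO_MISMATCHES: dict[str, tuple[tuple[int, int], tuple[int, int] | None]] = {
    "L1": ((0, 0), None),
    "L2_dMM": ((1, 1), (3, 3)),   # MM 1 vs 3 -> dMM = 2
    "L2_dTM": ((0, 1), (2, 2)),   # TM 1 vs 4 -> dTM = 3, dMM = 1
    "D_close": ((1, 1), (2, 2)),  # dMM = 1, dTM = 2: fails both
    "D_MM4": ((4, 2), None),
    "D_single": ((0, 0), None),
    "NA": ((0, 0), None),
}


@dataclass(frozen=True)
class RateProfile:
    """Planted heterozygosity rates in SNPs per kbp per region class."""

    autosome: float = 1.0
    hotspot: float = 3.0
    coldspot: float = 0.05
    par: float = 1.3
    x_body_female: float = 0.5  # male X body is hemizygous: rate 0


@dataclass(frozen=True)
class MarkerScenario:
    marker_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MARKER_SCENARIO_KINDS:
            raise ValueError(f"unknown marker scenario {self.kind!r}")

    @property
    def expected_category(self) -> str:
        return {"L1": "L", "L2_dMM": "L", "L2_dTM": "L", "NA": "NA"}.get(self.kind, "D")

    @property
    def expected_group(self) -> int | None:
        return {"L1": 1, "L2_dMM": 2, "L2_dTM": 2}.get(self.kind)


DEFAULT_PANEL = tuple(
    MarkerScenario(f"mk_{kind}", kind) for kind in MARKER_SCENARIO_KINDS
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_autosomes: int = 2
    autosome_length: int = 1_500_000
    x_length: int = 1_200_000
    par_length: int = 250_000
    rates: RateProfile = field(default_factory=RateProfile)
    spot_length: int = 200_000     # hotspot/coldspot length per autosome
    sex: str = "male"
    mean_depth: float = 30.0
    depth_noise: str = "poisson"   # 'poisson' | 'none'
    depth_noise_block: int = 1     # draw one Poisson value per this many bases
    draft_n50: int = 200_000
    draft_gap_size: int = 100
    draft_join_prob: float = 0.25
    panel_spec: tuple[MarkerScenario, ...] = DEFAULT_PANEL
    primer_length: int = 24
    amplicon_length: int = 200
    fail_fractions: tuple[tuple[str, float], ...] = (
        ("qual", 0.05), ("sp", 0.05), ("dp", 0.05), ("gq", 0.05),
    )
    hom_alt_fraction: float = 0.1
    indel_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.par_length < self.x_length:
            raise ValueError("par_length must be positive and below x_length")
        if any(r < 0 for r in vars(self.rates).values()):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class RegionTruth:
    scaffold: str
    start: int
    end: int
    region_class: str  # autosome | hotspot | coldspot | PAR | x_body


@dataclass(frozen=True)
class MarkerTruth:
    marker_id: str
    kind: str
    expected_category: str
    expected_group: int | None
    target_scaffold: str | None
    target_start: int | None
    decoy_scaffold: str | None
    decoy_start: int | None


@dataclass(frozen=True)
class VariantTruth:
    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: str
    is_snp: bool
    is_het: bool
    qual: float
    dp: int
    gq: int
    sp: int
    expect_pass: bool
    region_class: str


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    chrom: GenomeAssembly
    draft: GenomeAssembly
    x_scaffold: str
    par_interval: tuple[int, int]
    regions: list[RegionTruth]
    markers: list[MarkerTruth]
    panel: list[PrimerPair]
    # draft composition: (chrom scaffold, chrom start, chrom end,
    #                     draft scaffold, draft offset)
    draft_map: list[tuple[str, int, int, str, int]]

    def project_to_draft(self, scaffold: str, pos: int) -> tuple[str, int]:
        """Map a 1-based chromosome-level position to draft coordinates."""
        for c_scaf, c_start, c_end, d_scaf, d_off in self.draft_map:
            if c_scaf == scaffold and c_start < pos <= c_end:
                return d_scaf, pos - c_start + d_off
        raise KeyError(f"{scaffold}:{pos} not covered by draft map")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute k distinct positions with a different base each."""
    if k == 0:
        return seq
    arr = list(seq)
    for i in rng.choice(len(arr), size=k, replace=False):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _plant(chars: np.ndarray, pos: int, construct: str) -> None:
    chars[pos : pos + len(construct)] = np.frombuffer(
        construct.encode("ascii"), dtype=np.uint8
    )


def _build_construct(
    fwd: str, rev: str, mm: tuple[int, int], amplicon_length: int,
    rng: np.random.Generator, ff: bool = False,
) -> str:
    """Genome insert that yields one FR (or FF) amplicon of the given
    length with the given per-primer mismatch counts."""
    up = _mutate(fwd, mm[0], rng)
    down_primer = fwd if ff else rev
    down = revcomp(_mutate(down_primer, mm[1], rng))
    middle = amplicon_length - len(up) - len(down)
    if middle < 0:
        raise ValueError("amplicon_length too small for primer pair")
    filler = _random_seq(rng, middle).tobytes().decode("ascii")
    return up + filler + down


def _fragment_lengths(
    total: int, target_n50: int, rng: np.random.Generator
) -> list[int]:
    """Exponential fragment lengths tuned so the N50 lands near target."""
    # for exponential pieces the N50 sits near 1.68x the mean length
    mu = max(2000.0, target_n50 / 1.678)
    lengths: list[int] = []
    remaining = total
    while remaining > 0:
        piece = int(max(1000, rng.exponential(mu)))
        piece = min(piece, remaining)
        if remaining - piece < 1000:
            piece = remaining
        lengths.append(piece)
        remaining -= piece
    return lengths


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Chromosome-level and fragmented draft assemblies plus truth tables."""
    rng = np.random.default_rng(config.seed)
    scaffolds: list[tuple[str, str]] = []
    regions: list[RegionTruth] = []
    raw: dict[str, np.ndarray] = {}

    for i in range(config.n_autosomes):
        name = f"chr{i + 1}"
        raw[name] = _random_seq(rng, config.autosome_length)
        # one hotspot and one coldspot per autosome at fixed fractions
        hs = int(0.25 * config.autosome_length)
        cs = int(0.60 * config.autosome_length)
        spot = min(config.spot_length, config.autosome_length // 5)
        cuts = sorted([0, hs, hs + spot, cs, cs + spot, config.autosome_length])
        classes = ["autosome", "hotspot", "autosome", "coldspot", "autosome"]
        for (start, end), cls in zip(zip(cuts, cuts[1:]), classes):
            if end > start:
                regions.append(RegionTruth(name, start, end, cls))

    x_name = "chrX"
    raw[x_name] = _random_seq(rng, config.x_length)
    par_start = config.x_length - config.par_length
    par_interval = (par_start, config.x_length)
    regions.append(RegionTruth(x_name, 0, par_start, "x_body"))
    regions.append(RegionTruth(x_name, par_start, config.x_length, "PAR"))

    panel, markers = _plant_panel(config, raw, rng)

    for name in raw:
        scaffolds.append((name, raw[name].tobytes().decode("ascii")))
    chrom = GenomeAssembly(scaffolds)

    draft, draft_map = _fragment_assembly(config, chrom, rng)

    return SimulatedGenome(
        config=config,
        chrom=chrom,
        draft=draft,
        x_scaffold=x_name,
        par_interval=par_interval,
        regions=regions,
        markers=markers,
        panel=panel,
        draft_map=draft_map,
    )


def _plant_panel(
    config: SimulationConfig,
    raw: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[PrimerPair], list[MarkerTruth]]:
    """Generate primer pairs and write their target/decoy sites into the
    genome.  Targets go on chr1, decoys on the last autosome (or far
    downstream on chr1), spaced so products never cross constructs."""
    panel: list[PrimerPair] = []
    markers: list[MarkerTruth] = []
    if not config.panel_spec:
        return panel, markers
    target_scaf = "chr1"
    decoy_scaf = f"chr{config.n_autosomes}" if config.n_autosomes > 1 else "chr1"
    slot = 4 * (config.amplicon_length + 1000)
    t_off = 10_000
    d_off = 10_000 if decoy_scaf != target_scaf else t_off + slot * (len(config.panel_spec) + 1)
    need = max(t_off, d_off) + slot * (len(config.panel_spec) + 1)
    for scaf in (target_scaf, decoy_scaf):
        if raw[scaf].size < need:
            raise ValueError(
                f"autosome_length too small to plant {len(config.panel_spec)} markers"
            )
    for i, scenario in enumerate(config.panel_spec):
        fwd = _random_seq(rng, config.primer_length).tobytes().decode("ascii")
        rev = _random_seq(rng, config.primer_length).tobytes().decode("ascii")
        panel.append(PrimerPair(scenario.marker_id, fwd, rev, "synthetic", "planted"))
        target_mm, decoy_mm = _SCENARIO_MISMATCHES[scenario.kind]
        t_pos = d_pos = None
        if scenario.kind != "NA":
            t_pos = t_off + i * slot
            construct = _build_construct(
                fwd, rev, target_mm, config.amplicon_length, rng,
                ff=(scenario.kind == "D_single"),
            )
            _plant(raw[target_scaf], t_pos, construct)
        if decoy_mm is not None:
            d_pos = d_off + i * slot
            construct = _build_construct(
                fwd, rev, decoy_mm, config.amplicon_length + 100, rng
            )
            _plant(raw[decoy_scaf], d_pos, construct)
        markers.append(
            MarkerTruth(
                marker_id=scenario.marker_id,
                kind=scenario.kind,
                expected_category=scenario.expected_category,
                expected_group=scenario.expected_group,
                target_scaffold=target_scaf if t_pos is not None else None,
                target_start=t_pos,
                decoy_scaffold=decoy_scaf if d_pos is not None else None,
                decoy_start=d_pos,
            )
        )
    return panel, markers


def _fragment_assembly(
    config: SimulationConfig,
    chrom: GenomeAssembly,
    rng: np.random.Generator,
    max_tries: int = 30,
) -> tuple[GenomeAssembly, list[tuple[str, int, int, str, int]]]:
    """Fragment the chromosome-level sequence into a draft whose N50 is
    within 20% of the target, joining some neighbours with N spacers."""
    from .assembly_metrics import n50 as n50_of

    total = sum(len(s) for _, s in chrom)
    if config.draft_n50 > total // 2:
        raise ValueError("draft_n50 infeasible: exceeds half the genome size")
    target = config.draft_n50
    for _ in range(max_tries):
        state = rng.bit_generator.state  # rewind point for retries
        scaffolds: list[tuple[str, str]] = []
        draft_map: list[tuple[str, int, int, str, int]] = []
        counter = 0
        for c_name, seq in chrom:
            pieces = _fragment_lengths(len(seq), target, rng)
            offset = 0
            pending: list[tuple[int, int]] = []  # (chrom start, chrom end)
            for j, piece in enumerate(pieces):
                pending.append((offset, offset + piece))
                offset += piece
                last = j == len(pieces) - 1
                if last or rng.random() >= config.draft_join_prob:
                    counter += 1
                    d_name = f"scaf_{counter}"
                    parts: list[str] = []
                    d_off = 0
                    for c_start, c_end in pending:
                        if parts:
                            parts.append("N" * config.draft_gap_size)
                            d_off += config.draft_gap_size
                        parts.append(seq[c_start:c_end])
                        draft_map.append((c_name, c_start, c_end, d_name, d_off))
                        d_off += c_end - c_start
                    scaffolds.append((d_name, "".join(parts)))
                    pending = []
        achieved = n50_of(len(s) for _, s in scaffolds)
        if abs(achieved - config.draft_n50) <= 0.2 * config.draft_n50:
            return GenomeAssembly(scaffolds), draft_map
        rng.bit_generator.state = state
        rng.random(1)  # advance the stream before retrying
        target = int(target * config.draft_n50 / max(achieved, 1))
        target = max(2000, min(target, total // 2))
    raise ValueError(
        f"could not reach draft N50 {config.draft_n50} within 20% "
        f"after {max_tries} attempts"
    )


def _rate_for(config: SimulationConfig, region_class: str, sex: str) -> float:
    r = config.rates
    if region_class == "x_body":
        return 0.0 if sex == "male" else r.x_body_female
    return {
        "autosome": r.autosome,
        "hotspot": r.hotspot,
        "coldspot": r.coldspot,
        "PAR": r.par,
    }[region_class]


def simulate_variants(
    config: SimulationConfig,
    genome: SimulatedGenome,
    sex: str | None = None,
) -> list[VariantTruth]:
    """Place heterozygous SNPs by a piecewise-homogeneous Poisson process
    and draw QUAL/DP/GQ/SP spanning the filter thresholds.

    A configured fraction of records independently violates each
    threshold; ``expect_pass`` records the evaluated filter verdict.
    """
    sex = sex or config.sex
    rng = np.random.default_rng((config.seed, 1))
    fail = dict(config.fail_fractions)
    records: list[VariantTruth] = []
    seqs = dict(genome.chrom.scaffolds)
    for region in genome.regions:
        rate = _rate_for(config, region.region_class, sex)
        span = region.end - region.start
        n = rng.poisson(rate * span / 1000.0)
        if n == 0:
            continue
        positions = np.unique(rng.integers(region.start, region.end, size=n))
        for pos0 in positions:
            ref = seqs[region.scaffold][pos0]
            if ref == "N":
                continue
            alt_choices = [b for b in "ACGT" if b != ref]
            is_indel = rng.random() < config.indel_fraction
            alt = ref + alt_choices[rng.integers(0, 3)] if is_indel else alt_choices[rng.integers(0, 3)]
            is_het = rng.random() >= config.hom_alt_fraction
            qual = (
                float(rng.uniform(0, 20))
                if rng.random() < fail.get("qual", 0)
                else float(rng.uniform(30, 100))
            )
            dp = (
                int(rng.integers(0, 5))
                if rng.random() < fail.get("dp", 0)
                else int(max(5, rng.poisson(config.mean_depth)))
            )
            gq = (
                int(rng.integers(0, 20))
                if rng.random() < fail.get("gq", 0)
                else int(rng.integers(20, 100))
            )
            sp = (
                int(rng.integers(61, 100))
                if rng.random() < fail.get("sp", 0)
                else int(rng.integers(0, 61))
            )
            expect_pass = not (qual < 20.0 or sp > 60.0 or dp < 5.0 or gq < 20.0)
            records.append(
                VariantTruth(
                    scaffold=region.scaffold,
                    pos=int(pos0) + 1,
                    ref=ref,
                    alt=alt,
                    is_snp=not is_indel,
                    is_het=is_het,
                    qual=round(qual, 2),
                    dp=dp,
                    gq=gq,
                    sp=sp,
                    expect_pass=expect_pass,
                    region_class=region.region_class,
                )
            )
    records.sort(key=lambda r: (r.scaffold, r.pos))
    return records


def simulate_depth(
    config: SimulationConfig,
    genome: SimulatedGenome,
    sex: str | None = None,
) -> DepthTrack:
    """Depth track: autosomes and PAR at mean depth, male X body at half.

    With ``depth_noise='poisson'`` one Poisson value is drawn per
    ``depth_noise_block`` bases; 'none' gives the exact step function.
    """
    sex = sex or config.sex
    rng = np.random.default_rng((config.seed, 2))
    arrays: dict[str, np.ndarray] = {}
    par_start, par_end = genome.par_interval
    for name, seq in genome.chrom:
        n = len(seq)
        mean = np.full(n, config.mean_depth)
        if name == genome.x_scaffold and sex == "male":
            mean[:par_start] = config.mean_depth / 2.0
            mean[par_end:] = config.mean_depth / 2.0
        if config.depth_noise == "poisson":
            block = max(1, config.depth_noise_block)
            n_blocks = math.ceil(n / block)
            block_means = mean[::block][:n_blocks]
            noise = rng.poisson(block_means)
            arr = np.repeat(noise, block)[:n]
        elif config.depth_noise == "none":
            arr = mean
        else:
            raise ValueError(f"unknown depth_noise {config.depth_noise!r}")
        arrays[name] = arr
    return DepthTrack.from_arrays(arrays)


def simulate_panel(
    config: SimulationConfig, genome: SimulatedGenome
) -> tuple[list[PrimerPair], list[MarkerTruth]]:
    """Primer panel and truth categories for the sites planted at genome
    generation time."""
    return list(genome.panel), list(genome.markers)


def simulate_window_values(
    rate: float, n_windows: int, window_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Window het densities (SNPs/kbp) under a Poisson count model."""
    counts = rng.poisson(rate * window_size / 1000.0, size=n_windows)
    return counts / (window_size / 1000.0)


# ---------------------------------------------------------------------------
# plain-text writers

def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf_text(
    records: Sequence[VariantTruth],
    path: str | Path,
    contigs: dict[str, int],
    sample: str = "sample1",
) -> None:
    """Write truth records as a single-sample VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            '##FORMAT=<ID=SP,Number=1,Type=Integer,'
            'Description="Phred strand bias P-value">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for rec in records:
            gt = "0/1" if rec.is_het else "1/1"
            fh.write(
                f"{rec.scaffold}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t"
                f"{rec.qual:g}\t.\t.\tGT:DP:GQ:SP\t"
                f"{gt}:{rec.dp}:{rec.gq}:{rec.sp}\n"
            )


def write_panel_tsv(panel: Sequence[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tforward\treverse\tsource_species\tsource_publication\n")
        for p in panel:
            fh.write(
                f"{p.marker_id}\t{p.forward}\t{p.reverse}\t"
                f"{p.source_species}\t{p.source_publication}\n"
            )


def write_marker_truth_tsv(markers: Sequence[MarkerTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "marker_id\tkind\texpected_category\texpected_group\t"
            "target_scaffold\ttarget_start\tdecoy_scaffold\tdecoy_start\n"
        )
        for m in markers:
            fh.write(
                f"{m.marker_id}\t{m.kind}\t{m.expected_category}\t"
                f"{m.expected_group if m.expected_group is not None else '.'}\t"
                f"{m.target_scaffold or '.'}\t"
                f"{m.target_start if m.target_start is not None else '.'}\t"
                f"{m.decoy_scaffold or '.'}\t"
                f"{m.decoy_start if m.decoy_start is not None else '.'}\n"
            )


def write_variant_truth_tsv(records: Sequence[VariantTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "scaffold\tpos\tref\talt\tis_snp\tis_het\tqual\tdp\tgq\tsp\t"
            "expect_pass\tregion_class\n"
        )
        for r in records:
            fh.write(
                f"{r.scaffold}\t{r.pos}\t{r.ref}\t{r.alt}\t{int(r.is_snp)}\t"
                f"{int(r.is_het)}\t{r.qual:g}\t{r.dp}\t{r.gq}\t{r.sp}\t"
                f"{int(r.expect_pass)}\t{r.region_class}\n"
            )
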