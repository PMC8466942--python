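import numpy as np
import pytest

from chromdiv.assembly_metrics import GenomeAssembly
from chromdiv.str_localization import (
    Amplicon,
    IUPAC,
    MarkerCall,
    PanelSummary,
    PrimerPair,
    PrimerSite,
    classify_marker,
    find_primer_sites,
    localize_panel,
    pair_amplicons,
    panel_report,
    rank_amplicons,
    read_panel,
    revcomp,
)


def brute_force_sites(assembly, primer, max_mismatch=4):
    """All-position Hamming scan on both strands, IUPAC-aware on the
    primer side, genome N never matches."""
    out = set()
    for scaffold, seq in assembly:
        for query, strand in ((primer.upper(), "+"), (revcomp(primer).upper(), "-")):
            m = len(query)
            for pos in range(len(seq) - m + 1):
                mm = sum(
                    seq[pos + j] not in IUPAC[query[j]] for j in range(m)
                )
                if mm <= max_mismatch:
                    out.add((scaffold, pos, strand, mm))
    return out


def amp(mm_f, mm_r, length=200, orientation="FR", start=0, scaffold="s"):
    return Amplicon(scaffold, start, start + length, orientation, mm_f, mm_r)


PAIR = PrimerPair("mk1", "ACGTACGTACGT", "TTGCATTGCATT")


class TestFindPrimerSites:
    def test_exact_copy_found(self):
        primer = "AACCGGTTACGA"  # not palindromic
        genome = GenomeAssembly([("s", "TTTT" + primer + "GGGG")])
        sites = find_primer_sites(genome, primer)
        exact = [s for s in sites if s.mismatches == 0]
        assert [(s.start, s.strand) for s in exact] == [(4, "+")]

    def test_five_substitutions_no_hit(self, rng):
        primer = "ACGTACGTACGTACGTACGT"
        mutated = "TGACT" + primer[5:]  # 5 leading mismatches vs primer
        genome = GenomeAssembly([("s", "CCCCC" + mutated + "CCCCC")])
        hits = [
            s for s in find_primer_sites(genome, primer) if s.mismatches <= 4
        ]
        brute = brute_force_sites(genome, primer)
        assert {(h.scaffold, h.start, h.strand, h.mismatches) for h in hits} == brute

    def test_genome_n_counts_as_mismatch(self):
        genome = GenomeAssembly([("s", "ACGTNCGTACGT")])
        (hit,) = [
            s for s in find_primer_sites(genome, "ACGTACGTACGT") if s.strand == "+"
        ]
        assert hit.mismatches == 1

    def test_iupac_primer_matches_expansion(self):
        # R = A or G
        genome = GenomeAssembly([("s", "ACGTACGTACGTA")])
        hits = [
            s
            for s in find_primer_sites(genome, "RCGTACGTACGT")
            if s.strand == "+" and s.start == 0
        ]
        assert hits[0].mismatches == 0

    def test_non_iupac_primer_rejected(self):
        genome = GenomeAssembly([("s", "ACGT" * 10)])
        with pytest.raises(ValueError, match="non-IUPAC"):
            find_primer_sites(genome, "ACGTXCGTACGT")

    def test_matches_brute_force_on_random_genome(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=3000, p=[0.24] * 4 + [0.04]))
        genome = GenomeAssembly([("s1", seq[:1500]), ("s2", seq[1500:])])
        primer = seq[700:712]  # planted 12-mer: guaranteed neighborhood hits
        got = {
            (h.scaffold, h.start, h.strand, h.mismatches)
            for h in find_primer_sites(genome, primer)
        }
        assert got == brute_force_sites(genome, primer)

    def test_minus_strand_coordinates(self):
        primer = "ACGTACGTACGT"
        genome = GenomeAssembly([("s", "GG" + revcomp(primer) + "AA")])
        (hit,) = [s for s in find_primer_sites(genome, primer) if s.strand == "-"]
        assert (hit.start, hit.end) == (2, 14)


class TestPairAmplicons:
    def site(self, start, strand, mm=0, length=12, scaffold="s"):
        return PrimerSite(scaffold, start, strand, mm, length)

    def test_fr_arithmetic(self):
        fwd = [self.site(100, "+", mm=1)]
        rev = [self.site(338, "-", mm=2)]  # footprint ends at 350
        (a,) = pair_amplicons(fwd, rev)
        assert (a.start, a.end, a.length, a.orientation) == (100, 350, 250, "FR")
        assert (a.fwd_mismatches, a.rev_mismatches) == (1, 2)
        assert (a.mm_score, a.tm_score) == (2, 3)

    def test_length_bounds(self):
        fwd = [self.site(0, "+")]
        rev_too_far = [self.site(989, "-")]  # span 1001
        assert pair_amplicons(fwd, rev_too_far) == []
        rev_ok = [self.site(988, "-")]  # span 1000
        assert len(pair_amplicons(fwd, rev_ok)) == 1

    def test_min_length(self):
        fwd = [self.site(0, "+")]
        assert pair_amplicons(fwd, [self.site(37, "-")]) == []  # span 49
        assert len(pair_amplicons(fwd, [self.site(38, "-")])) == 1  # span 50

    def test_ff_product_flagged_single_primer(self):
        fwd = [self.site(0, "+"), self.site(188, "-")]
        (a,) = pair_amplicons(fwd, [])
        assert a.orientation == "FF"
        assert a.single_primer

    def test_rf_orientation(self):
        rev = [self.site(10, "+")]
        fwd = [self.site(200, "-")]
        (a,) = pair_amplicons(fwd, rev)
        assert a.orientation == "RF"

    def test_different_scaffolds_never_pair(self):
        fwd = [self.site(0, "+", scaffold="a")]
        rev = [self.site(200, "-", scaffold="b")]
        assert pair_amplicons(fwd, rev) == []


class TestRankAmplicons:
    def test_mm_primary(self):
        first = amp(1, 1, length=300)  # MM1 TM2
        second = amp(3, 0, length=120)  # MM3 TM3
        assert rank_amplicons([second, first])[0] == first

    def test_tm_breaks_mm_ties(self):
        a = amp(2, 0, length=500)  # MM2 TM2
        b = amp(2, 2, length=100)  # MM2 TM4
        assert rank_amplicons([b, a])[0] == a

    def test_length_breaks_full_score_tie(self):
        a = amp(1, 1, length=100)
        b = amp(1, 1, length=300)
        assert rank_amplicons([b, a])[0] == a

    def test_stable_on_full_tie(self):
        a = amp(1, 1, length=200, start=0)
        b = amp(1, 1, length=200, start=5000)
        assert rank_amplicons([a, b]) == [a, b]
        assert rank_amplicons([b, a]) == [b, a]


class TestClassifyMarker:
    def test_empty_is_na(self):
        call = classify_marker(PAIR, [])
        assert (call.category, call.group, call.chosen) == ("NA", None, None)

    def test_single_fr_mm2_is_l1(self):
        call = classify_marker(PAIR, [amp(2, 1)])
        assert (call.category, call.group) == ("L", 1)

    def test_group2_via_delta_mm(self):
        call = classify_marker(PAIR, [amp(1, 0), amp(3, 2, length=400)])
        assert (call.category, call.group) == ("L", 2)

    def test_group2_via_delta_tm(self):
        # MM 1 vs 2 (dMM=1) but TM 1 vs 4 (dTM=3)
        call = classify_marker(PAIR, [amp(1, 0), amp(2, 2, length=400)])
        assert (call.category, call.group) == ("L", 2)

    def test_separation_fails_is_d(self):
        # dMM = 1, dTM = 1
        call = classify_marker(PAIR, [amp(1, 1), amp(2, 1, length=400)])
        assert call.category == "D"

    def test_top_mm4_is_d(self):
        call = classify_marker(PAIR, [amp(4, 2)])
        assert call.category == "D"

    def test_single_primer_top_is_d(self):
        call = classify_marker(PAIR, [amp(0, 0, orientation="FF")])
        assert call.category == "D"

    def test_partition_complete(self, rng):
        """Every random amplicon list maps to exactly one category."""
        for _ in range(100):
            n = int(rng.integers(0, 4))
            amps = [
                amp(
                    int(rng.integers(0, 5)),
                    int(rng.integers(0, 5)),
                    length=int(rng.integers(50, 1001)),
                    orientation=str(rng.choice(["FR", "RF", "FF"])),
                    start=1000 * i,
                )
                for i in range(n)
            ]
            call = classify_marker(PAIR, amps)
            assert call.category in ("NA", "D", "L")
            assert (call.category == "NA") == (not amps)


class TestStrandSymmetry:
    def test_revcomp_genome_preserves_categories(self, small_config):
        from chromdiv import synthetic_data as sd

        genome = sd.simulate_genome(small_config)
        fwd_calls = localize_panel(genome.chrom, genome.panel)
        flipped = GenomeAssembly(
            [(name, revcomp(seq)) for name, seq in genome.chrom]
        )
        rev_calls = localize_panel(flipped, genome.panel)
        for f, r in zip(fwd_calls, rev_calls):
            assert (f.category, f.group) == (r.category, r.group)


class TestPanelReport:
    def calls(self, spec):
        """spec: list of (category, scaffold)."""
        out = []
        for i, (cat, scaffold) in enumerate(spec):
            chosen = (
                Amplicon(scaffold, 10, 210, "FR", 0, 0) if cat == "L" else None
            )
            out.append(MarkerCall(f"m{i}", cat, 1 if cat == "L" else None, chosen))
        return out

    def assembly(self, n_scaffolds=4):
        # descending lengths so C-scaffold designation is deterministic
        return GenomeAssembly(
            [(f"c{i}", "A" * (1000 - i * 100)) for i in range(n_scaffolds)]
        )

    def test_table_arithmetic(self):
        calls = self.calls(
            [("L", "c0"), ("L", "c0"), ("L", "c1"), ("NA", None), ("D", None)]
        )
        s = panel_report(calls, self.assembly(), n_chromosomes=3)
        assert (s.n_localized, s.n_not_amplified, s.n_declined) == (3, 1, 1)
        assert s.n_chrom_with_markers == 2
        assert s.n_chrom_without_markers == 1
        assert s.overall_density == pytest.approx(1.0)
        assert s.labeled_density == pytest.approx(1.5)

    def test_all_na(self):
        s = panel_report(self.calls([("NA", None)] * 3), self.assembly(), 4)
        assert s.overall_density == 0
        assert s.labeled_density == 0
        assert s.n_chrom_with_markers == 0

    def test_unplaced_hits_not_counted_as_labeled(self):
        calls = self.calls([("L", "c3")])  # c3 is not among the 2 C-scaffolds
        s = panel_report(calls, self.assembly(), n_chromosomes=2)
        assert s.n_localized == 1  # still localized
        assert s.n_chrom_with_markers == 0  # but on an unplaced scaffold

    def test_n_chromosomes_bounds(self):
        with pytest.raises(ValueError):
            panel_report([], self.assembly(2), n_chromosomes=3)

    def test_category_counts_sum_to_panel_size(self, small_config):
        from chromdiv import synthetic_data as sd

        genome = sd.simulate_genome(small_config)
        calls = localize_panel(genome.chrom, genome.panel)
        s = panel_report(calls, genome.chrom, n_chromosomes=2)
        assert s.n_localized + s.n_not_amplified + s.n_declined == len(genome.panel)


class TestPanelIO:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "marker_id\tforward\treverse\tsource_species\n"
            "mk1\tACGTACGTACGT\tTTGCATTGCATT\tstone marten\n"
        )
        (pair,) = read_panel(p)
        assert pair.marker_id == "mk1"
        assert pair.source_species == "stone marten"

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            PrimerPair("bad", "ACGTACG", "TTGCATTGCATT")
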