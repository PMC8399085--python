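"""Motif discovery, the two scan engines, and BED/TSV emission."""

import re

import pytest

from pasedit import (
    EditorSpec,
    PASMotifSpec,
    build_editable_regex,
    find_motif_sites,
    oracle_scan,
    oracle_site_guides,
    read_scan_bed,
    scan,
    write_bed,
    write_guides_tsv,
)
from pasedit._seq import revcomp

from conftest import DUX4_LIKE, random_genome


class TestFindMotifSites:
    def test_single_plus_occurrence(self, motifs):
        sites = find_motif_sites("AATAAA", motifs)
        assert [(s.interval, s.strand, s.hexamer) for s in sites] == [((0, 6), "+", "AATAAA")]

    def test_reverse_complement_occurrence(self, motifs):
        sites = find_motif_sites("TTTAAT", motifs)
        assert [(s.interval, s.strand, s.hexamer) for s in sites] == [((0, 6), "-", "ATTAAA")]

    def test_overlapping_occurrences_match_sliding_oracle(self, motifs):
        """Site set equals a brute-force 6-mer sliding comparison, including
        overlapping occurrences in AT-rich sequence."""
        for seed in range(8):
            seq = random_genome(seed, 3000, at_rich=True)
            expected = set()
            for m in motifs:
                for i in range(len(seq) - 5):
                    if seq[i:i + 6] == m.hexamer:
                        expected.add((i, i + 6, "+", m.hexamer))
                    if seq[i:i + 6] == revcomp(m.hexamer):
                        expected.add((i, i + 6, "-", m.hexamer))
            got = {(s.interval[0], s.interval[1], s.strand, s.hexamer)
                   for s in find_motif_sites(seq, motifs)}
            assert got == expected

    def test_empty_sequence(self, motifs):
        assert find_motif_sites("", motifs) == []


class TestEditableRegex:
    def test_coding_pattern_structure(self, editor):
        pattern = build_editable_regex(editor, PASMotifSpec("ATTAAA"), "coding")
        assert pattern.startswith("ATTAAA")
        assert "{10,16}" in pattern
        rx = re.compile(pattern)
        assert rx.match("ATTAAA" + "A" * 10 + "TGG")
        assert rx.match("ATTAAA" + "A" * 16 + "AGG")
        assert not rx.match("ATTAAA" + "A" * 9 + "TGGT")
        assert not rx.match("ATTAAA" + "A" * 17 + "TG")

    def test_template_pattern_is_plus_strand_mirror(self, editor):
        pattern = build_editable_regex(editor, PASMotifSpec("ATTAAA"), "template")
        assert pattern.startswith("CC")
        assert pattern.endswith("ATTAAA")
        assert "{10,14}" in pattern
        assert re.compile(pattern).match("CCA" + "T" * 12 + "ATTAAA")

    def test_unreachable_geometry_is_domain_error(self):
        editor = EditorSpec("deep", window=(20, 20))  # coding gaps would be negative
        with pytest.raises(ValueError):
            build_editable_regex(editor, PASMotifSpec("AATAAA"), "coding")


class TestEngines:
    def test_empty_collection(self, editor, motifs):
        assert scan({}, editor, motifs) == []

    @pytest.mark.parametrize("at_rich", [False, True])
    def test_three_way_equivalence_random_genomes(self, editor, motifs, at_rich):
        """Direct engine, regex engine and the exhaustive oracle agree on
        site sets and editability flags."""
        for seed in range(10):
            seq = random_genome(seed * 7 + int(at_rich), 2000, at_rich=at_rich)
            genome = {"g": seq}
            direct = scan(genome, editor, motifs, engine="direct")
            rgx = scan(genome, editor, motifs, engine="regex")
            guides = oracle_site_guides(genome, editor, motifs)
            assert {r.site.key for r in direct} == {r.site.key for r in rgx} == set(guides)
            d_flags = {r.site.key: r.editable for r in direct}
            x_flags = {r.site.key: r.editable for r in rgx}
            o_flags = {k: n > 0 for k, n in guides.items()}
            assert d_flags == x_flags == o_flags
            d_counts = {r.site.key: len(r.guides) for r in direct}
            assert d_counts == guides

    def test_equivalence_on_tiny_sequences(self, editor, motifs):
        """Sequence ends: placements may not run off the sequence, and both
        engines must agree there too."""
        for seed in range(30):
            seq = random_genome(1000 + seed, 40 + seed * 3, at_rich=True)
            genome = {"t": seq}
            d = {r.site.key: r.editable for r in scan(genome, editor, motifs)}
            x = {r.site.key: r.editable for r in scan(genome, editor, motifs, engine="regex")}
            o = oracle_scan(genome, editor, motifs)
            assert d == x
            assert {k for k, v in d.items() if v} == o

    def test_reverse_complement_invariance(self, editor, motifs):
        """Scanning revcomp(genome) yields the coordinate-mirrored records."""
        for seed in range(5):
            seq = random_genome(seed + 500, 2000, at_rich=True)
            n = len(seq)
            fwd = scan({"g": seq}, editor, motifs)
            rev = scan({"g": revcomp(seq)}, editor, motifs)
            mirror = {
                ("g", n - r.site.interval[1], n - r.site.interval[0],
                 "-" if r.site.strand == "+" else "+", r.site.hexamer, r.editable)
                for r in rev
            }
            assert {
                (r.site.chrom, *r.site.interval, r.site.strand, r.site.hexamer, r.editable)
                for r in fwd
            } == mirror

    def test_records_stay_inside_bounds_and_n_free(self, editor, motifs):
        seq = "N" * 3 + random_genome(9, 1000) + "N" * 3
        for r in scan({"g": seq}, editor, motifs):
            for g in r.guides:
                ps, pe = g.placement.protospacer_interval
                assert 0 <= ps < pe <= len(seq)
                assert "N" not in g.protospacer_seq and "N" not in g.pam_seq

    def test_softmask_exclusion(self, editor, motifs):
        seq = DUX4_LIKE.lower()
        assert scan({"g": seq}, editor, motifs)[0].editable  # uppercased by default
        assert scan({"g": seq}, editor, motifs, include_softmasked=False) == []

    def test_unknown_engine_rejected(self, editor, motifs):
        with pytest.raises(ValueError):
            scan({"g": "AATAAA"}, editor, motifs, engine="bogus")


class TestWriters:
    def test_empty_records_give_valid_empty_files(self, tmp_path):
        bed, tsv = tmp_path / "x.bed", tmp_path / "x.tsv"
        write_bed([], bed)
        write_guides_tsv([], tsv)
        assert bed.read_text() == ""
        assert tsv.read_text().startswith("chrom\t")
        assert read_scan_bed(bed) == []

    def test_score_is_guide_count_and_rows_per_guide(self, editor, motifs, tmp_path):
        # two PAMs at distinct gaps -> two guide candidates for one site
        seq = "ACAC" + "ATTAAA" + "ATCATCATCA" + "AGG" + "TCA" + "TGG" + "ATCATC"
        records = scan({"chr1": seq}, editor, motifs)
        (rec,) = [r for r in records if r.site.interval == (4, 10)]
        assert len(rec.guides) == 2
        bed, tsv = tmp_path / "s.bed", tmp_path / "s.tsv"
        write_bed(records, bed)
        write_guides_tsv(records, tsv)
        line = bed.read_text().splitlines()[0].split("\t")
        assert line == ["chr1", "4", "10", "ATTAAA", "2", "+"]
        rows = tsv.read_text().splitlines()
        assert len(rows) == 1 + sum(len(r.guides) for r in records)

    def test_bed_round_trip(self, editor, motifs, tmp_path):
        seq = random_genome(3, 3000, at_rich=True)
        records = scan({"c": seq}, editor, motifs)
        path = tmp_path / "rt.bed"
        write_bed(records, path)
        back = read_scan_bed(path)
        assert {(r.site.key, r.editable) for r in back} == {
            (r.site.key, r.editable) for r in records
        }
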