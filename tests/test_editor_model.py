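"""Placement geometry, gap ranges and predicted edits."""

import pytest
from hypothesis import assume, given, settings, strategies as st

from pasedit import (
    EditorSpec,
    MotifSite,
    PASMotifSpec,
    enumerate_guides_for_site,
    gap_range,
    placements_for_target,
    predicted_edited_hexamer,
)
from pasedit._seq import matches_iupac, revcomp

from conftest import DUX4_LIKE, random_genome

dna = st.text(alphabet="ACGT", min_size=30, max_size=80)


def brute_force_placements(target_pos, target_strand, editor, seq):
    """Independent enumeration over every protospacer start on the target
    strand, filtered by PAM match and window containment."""
    L, npam = editor.protospacer_len, len(editor.pam)
    lo, hi = editor.window
    found = set()
    for start in range(len(seq)):
        proto = (start, start + L)
        if target_strand == "+":
            pam = (start + L, start + L + npam)
            if proto[0] < 0 or pam[1] > len(seq):
                continue
            w = target_pos - start + 1
            pam_seq = seq[pam[0]:pam[1]]
        else:
            pam = (start - npam, start)
            if pam[0] < 0 or proto[1] > len(seq):
                continue
            w = proto[1] - target_pos
            pam_seq = revcomp(seq[pam[0]:pam[1]])
        if not (lo <= w <= hi):
            continue
        if not matches_iupac(pam_seq, editor.pam):
            continue
        if any(b not in "ACGT" for b in seq[proto[0]:proto[1]]):
            continue
        found.add((target_strand, w, proto, pam))
    return found


class TestPlacements:
    def test_dux4_like_single_placement(self, editor):
        """The A at hexamer position 4 with a TGG 14 nt downstream admits
        exactly one placement, at window position 4."""
        placements = placements_for_target(3, "+", editor, DUX4_LIKE)
        assert len(placements) == 1
        (pl,) = placements
        assert pl.window_pos == 4
        assert pl.protospacer_interval == (0, 20)
        assert DUX4_LIKE[pl.pam_interval[0]:pl.pam_interval[1]] == "TGG"

    def test_no_g_means_no_ngg_placement(self, editor):
        seq = "ATTAAA" + "AT" * 20
        assert placements_for_target(3, "+", editor, seq) == []

    def test_out_of_range_target_rejected(self, editor):
        with pytest.raises(ValueError):
            placements_for_target(99, "+", editor, "ATTAAA")

    def test_non_source_base_rejected(self, editor):
        with pytest.raises(ValueError):
            placements_for_target(1, "+", editor, "ATTAAA" + "A" * 30)

    def test_ambiguous_base_warns_and_yields_nothing(self, editor):
        seq = "ATTAN" + "A" * 30
        with pytest.warns(UserWarning):
            assert placements_for_target(4, "+", editor, seq) == []

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("strand", "+-")
    def test_matches_brute_force_enumeration(self, editor, seed, strand):
        """Every source base of a random 200-nt sequence yields exactly the
        brute-force placement set, on both strands."""
        seq = random_genome(seed, 200)
        for pos, base in enumerate(seq):
            strand_base = base if strand == "+" else revcomp(base)
            if strand_base != editor.source_base:
                continue
            got = {
                (p.guide_strand, p.window_pos, p.protospacer_interval, p.pam_interval)
                for p in placements_for_target(pos, strand, editor, seq)
            }
            assert got == brute_force_placements(pos, strand, editor, seq)

    def test_emitted_placements_verify_against_reference(self, editor):
        """Re-reading the reference confirms PAM match, source base at the
        window position, and protospacer/PAM adjacency."""
        seq = random_genome(42, 500)
        for pos, base in enumerate(seq):
            if base != editor.source_base:
                continue
            for pl in placements_for_target(pos, "+", editor, seq):
                ps, pe = pl.protospacer_interval
                qs, qe = pl.pam_interval
                assert qs == pe and qe - qs == len(editor.pam)
                assert matches_iupac(seq[qs:qe], editor.pam)
                assert seq[ps + pl.window_pos - 1] == editor.source_base
                assert ps + pl.window_pos - 1 == pos


class TestGapRange:
    def derive_by_placement_enumeration(self, editor, motif, mode):
        """Re-derive the gap range by planting a lone PAM at every candidate
        gap and asking whether any placement reaches the hexamer."""
        pad = "AC" * 15  # no GG/CC, no motifs
        hexamer = motif.hexamer
        valid = []
        for g in range(0, 25):
            if mode == "coding":
                seq = pad + hexamer + "AC" * 15
                h = len(pad)
                seq = seq[: h + 6 + g] + "AGG" + seq[h + 6 + g + 3:]
                positions = motif.coding_disruptable
                strand = "+"
            else:
                # TCCA: the leading T insulates the CC from a pad C, so the
                # planted PAM can only be read at gap g
                seq = pad + hexamer + "AC" * 15
                h = len(pad)
                seq = seq[: h - g - 4] + "TCCA" + seq[h - g:]
                positions = motif.template_disruptable
                strand = "-"
            hits = []
            for p in positions:
                coord = h + p - 1
                hits += placements_for_target(coord, strand, editor, seq)
            if hits:
                valid.append(g)
        assert valid == list(range(min(valid), max(valid) + 1))
        return (min(valid), max(valid))

    @pytest.mark.parametrize("hexamer", ["AATAAA", "ATTAAA"])
    @pytest.mark.parametrize("mode", ["coding", "template"])
    def test_gap_range_equals_brute_force(self, editor, hexamer, mode):
        motif = PASMotifSpec(hexamer)
        assert gap_range(editor, motif, mode) == self.derive_by_placement_enumeration(
            editor, motif, mode
        )

    def test_collapsed_window_coding(self):
        editor = EditorSpec("narrow", window=(4, 4))
        assert gap_range(editor, PASMotifSpec("ATTAAA"), "coding") == (14, 16)

    def test_empty_disruptable_set_is_domain_error(self, editor):
        motif = PASMotifSpec("AATAAA", template_disruptable=frozenset())
        with pytest.raises(ValueError):
            gap_range(editor, motif, "template")


class TestPredictedHexamer:
    @pytest.mark.parametrize(
        "hexamer,pos,mode,expected",
        [
            ("ATTAAA", 4, "coding", "ATTGAA"),
            ("ATTAAA", 3, "template", "ATCAAA"),
            ("AATAAA", 5, "coding", "AATAGA"),
            ("AATAAA", 6, "coding", "AATAAG"),
            ("AATAAA", 3, "template", "AACAAA"),
        ],
    )
    def test_substitutions(self, hexamer, pos, mode, expected):
        assert predicted_edited_hexamer(PASMotifSpec(hexamer), pos, mode) == expected

    def test_non_disruptable_position_rejected(self):
        with pytest.raises(ValueError):
            predicted_edited_hexamer(PASMotifSpec("AATAAA"), 1, "coding")

    def test_every_predicted_mutant_leaves_the_motif_set(self, motifs):
        """Disruption property: every possible edit produces a hexamer that
        is no longer a canonical PAS motif."""
        hexamers = {m.hexamer for m in motifs}
        for m in motifs:
            for mode in ("coding", "template"):
                for p in m.disruptable(mode):
                    assert predicted_edited_hexamer(m, p, mode) not in hexamers


class TestSiteEnumeration:
    def test_dux4_like_guide_captures_last_three_adenines(self, editor):
        site = MotifSite("s", (0, 6), "+", "ATTAAA")
        guides = enumerate_guides_for_site(site, editor, PASMotifSpec("ATTAAA"), DUX4_LIKE)
        assert len(guides) == 1
        (g,) = guides
        assert g.hexamer_positions == {4, 5, 6}
        assert dict(g.captured_positions) == {4: 4, 5: 5, 6: 6}
        assert g.predicted_hexamers == {"ATTGAA", "ATTAGA", "ATTAAG"}
        assert g.pam_seq == "TGG"

    def test_template_guide_predicts_atcaaa(self, editor):
        # CCN placed 12 nt 5' of the hexamer start: gap = 12 - 3 = 9? No:
        # gap is measured PAM end -> hexamer start, so CC at -12 gives gap 10.
        seq = "CCA" + "AC" * 5 + "ATTAAA" + "AC" * 12
        site = MotifSite("s", (13, 19), "+", "ATTAAA")
        guides = enumerate_guides_for_site(site, editor, PASMotifSpec("ATTAAA"), seq)
        template = [g for g in guides if g.strand_mode == "template"]
        assert len(template) == 1
        assert template[0].predicted_hexamers == {"ATCAAA"}
        assert template[0].placement.guide_strand == "-"

    def test_hexamer_mismatch_rejected(self, editor):
        site = MotifSite("s", (0, 6), "+", "ATCAAA")
        with pytest.raises(ValueError, match="hexamer-mismatch"):
            enumerate_guides_for_site(site, editor, PASMotifSpec("ATTAAA"), "ATCAAA" + "A" * 20)

    def test_one_placement_two_positions_one_candidate(self, editor):
        """A window spanning several disruptable adenines yields one merged
        candidate, never duplicates."""
        guides = enumerate_guides_for_site(
            MotifSite("s", (0, 6), "+", "ATTAAA"), editor, PASMotifSpec("ATTAAA"), DUX4_LIKE
        )
        assert len(guides) == 1 and len(guides[0].captured_positions) == 3


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=dna, data=st.data())
def test_window_monotonicity(seq, data):
    """Enlarging the activity window never removes a placement."""
    positions = [i for i, b in enumerate(seq) if b == "A"]
    assume(positions)
    pos = data.draw(st.sampled_from(positions))
    lo = data.draw(st.integers(2, 10))
    hi = data.draw(st.integers(lo, 18))
    small = EditorSpec("s", window=(lo, hi))
    big = EditorSpec("b", window=(max(1, lo - 1), hi + 1))
    got_small = {
        (p.window_pos, p.protospacer_interval) for p in placements_for_target(pos, "+", small, seq)
    }
    got_big = {
        (p.window_pos, p.protospacer_interval) for p in placements_for_target(pos, "+", big, seq)
    }
    assert got_small <= got_big


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=dna, data=st.data())
def test_strand_symmetry(seq, data):
    """Placements on the reverse-complemented sequence with mirrored
    coordinates are exactly the mirrored placement set."""
    positions = [i for i, b in enumerate(seq) if b == "A"]
    assume(positions)
    pos = data.draw(st.sampled_from(positions))
    editor = EditorSpec("e")
    n = len(seq)
    fwd = placements_for_target(pos, "+", editor, seq)
    rev = placements_for_target(n - 1 - pos, "-", editor, revcomp(seq))
    mirrored = {
        (
            p.window_pos,
            (n - p.protospacer_interval[1], n - p.protospacer_interval[0]),
            (n - p.pam_interval[1], n - p.pam_interval[0]),
        )
        for p in rev
    }
    assert {
        (p.window_pos, p.protospacer_interval, p.pam_interval) for p in fwd
    } == mirrored
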