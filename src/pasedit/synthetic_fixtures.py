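"""Deterministic synthetic genomes with planted PAS sites and off-target
loci, plus the brute-force oracles used as ground truth.

The generator emits a genome in which every editable PAS, every decoy and
every near-match off-target locus is planted on purpose, and the
background is actively scrubbed so that no *accidental* canonical-hexamer
occurrence or near-match to the off-target query survives outside the
plants.  Before a fixture is emitted it must pass a self-consistency
gate: the exhaustive oracles re-scan the finished sequence and their
verdict has to equal the planting manifest exactly; otherwise the build
is retried from a derived seed.

Plant categories
----------------
``coding_editable``    canonical hexamer + NGG at an in-range gap (10-16 nt)
``template_editable``  CCN + in-range gap (10-14 nt) + canonical hexamer
``no_pam_decoy``       canonical hexamer inside GG/CC-free guard flanks
``wrong_gap_decoy``    canonical hexamer with the only GG at gap 18 (out of range)
``pseudo_motif``       ATCAAA + PAM at a valid gap (never a site: wrong hexamer)
``other_motif``        a non-canonical annotatable hexamer (default AGTAAA)
``offtarget``          protospacer variant with chosen mismatches + PAM

The oracles (:func:`oracle_scan`, :func:`oracle_site_guides`,
:func:`oracle_near_matches`) are deliberately unoptimised, enumerate every
(position, strand, disruptable position, window position) combination
from first principles, and share no matching code with the scan engines
or the off-target module: they keep their own complement and IUPAC
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .editor_model import EditorSpec, PASMotifSpec
from .offtarget import OffTargetQuery

# --- independent oracle primitives (no shared code with the engines) --------

_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _oracle_revcomp(seq: str) -> str:
    return "".join(_ORACLE_COMP.get(b, "N") for b in reversed(seq))


def _oracle_pam_ok(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    for b, sym in zip(seq, pattern):
        if b not in "ACGT" or b not in _ORACLE_IUPAC[sym]:
            return False
    return True


def _oracle_clean(seq: str) -> bool:
    return all(b in "ACGT" for b in seq)


SiteKey = tuple[str, int, int, str]


def oracle_site_guides(
    genome: Mapping[str, str],
    editor: EditorSpec,
    motifs: Sequence[PASMotifSpec],
) -> dict[SiteKey, int]:
    """Every motif occurrence mapped to its exhaustive guide count.

    Guides are distinct (guide strand, protospacer start) placements found
    by enumerating every hexamer position x disruptable position x window
    position on both strands and checking PAM, bounds and ambiguity codes
    directly.
    """
    L = editor.protospacer_len
    npam = len(editor.pam)
    lo, hi = editor.window
    out: dict[SiteKey, set[tuple[str, int]]] = {}
    for chrom, raw in genome.items():
        seq = str(raw).upper()
        n = len(seq)
        for i in range(n - 5):
            word = seq[i : i + 6]
            for motif in motifs:
                for strand in "+-":
                    expected = motif.hexamer if strand == "+" else _oracle_revcomp(motif.hexamer)
                    if word != expected:
                        continue
                    key = (chrom, i, i + 6, strand)
                    guides = out.setdefault(key, set())
                    for mode in ("coding", "template"):
                        positions = (
                            motif.coding_disruptable if mode == "coding" else motif.template_disruptable
                        )
                        if strand == "+":
                            guide_strand = "+" if mode == "coding" else "-"
                        else:
                            guide_strand = "-" if mode == "coding" else "+"
                        for p in positions:
                            t = i + p - 1 if strand == "+" else i + 6 - p
                            for w in range(lo, hi + 1):
                                if guide_strand == "+":
                                    ps = t - w + 1
                                    proto = (ps, ps + L)
                                    pam = (ps + L, ps + L + npam)
                                    if proto[0] < 0 or pam[1] > n:
                                        continue
                                    pam_seq = seq[pam[0] : pam[1]]
                                else:
                                    ps = t + w - L
                                    proto = (ps, ps + L)
                                    pam = (ps - npam, ps)
                                    if pam[0] < 0 or proto[1] > n:
                                        continue
                                    pam_seq = _oracle_revcomp(seq[pam[0] : pam[1]])
                                if not _oracle_pam_ok(pam_seq, editor.pam):
                                    continue
                                if not _oracle_clean(seq[proto[0] : proto[1]]):
                                    continue
                                guides.add((guide_strand, proto[0]))
    return {key: len(gs) for key, gs in out.items()}


def oracle_scan(
    genome: Mapping[str, str],
    editor: EditorSpec,
    motifs: Sequence[PASMotifSpec],
) -> set[SiteKey]:
    """The editable-site set: motif occurrences with >= 1 valid guide."""
    return {key for key, n in oracle_site_guides(genome, editor, motifs).items() if n > 0}


OTKey = tuple[str, int, int, str, tuple[int, ...]]


def oracle_near_matches(genome: Mapping[str, str], query: OffTargetQuery) -> set[OTKey]:
    """Sliding-window Hamming comparison at every position and strand.

    Returns (chrom, protospacer start, protospacer end, strand, mismatch
    positions).  Independent of the off-target module: the minus strand is
    handled in place by complementing the query, not by scanning a
    reverse-complemented copy.
    """
    L = len(query.protospacer)
    npam = len(query.pam)
    hits: set[OTKey] = set()
    for chrom, raw in genome.items():
        seq = str(raw).upper()
        n = len(seq)
        # plus strand: protospacer then PAM, left to right
        for i in range(n - L - npam + 1):
            pam = seq[i + L : i + L + npam]
            if not _oracle_pam_ok(pam, query.pam):
                continue
            window = seq[i : i + L]
            if not _oracle_clean(window):
                continue
            mism = tuple(
                k + 1 for k in range(L) if window[k] != query.protospacer[k]
            )
            if len(mism) <= query.max_mismatches:
                hits.add((chrom, i, i + L, "+", mism))
        # minus strand: PAM (revcomp'd) immediately left of the protospacer
        rc_query = _oracle_revcomp(query.protospacer)
        rc_pam = _oracle_revcomp(query.pam)
        for i in range(npam, n - L + 1):
            pam_plus = seq[i - npam : i]
            # plus-strand bases must match the reverse-complemented pattern
            ok = len(pam_plus) == npam and all(
                b in "ACGT" and b in _ORACLE_IUPAC[sym]
                for b, sym in zip(pam_plus, rc_pam)
            )
            if not ok:
                continue
            window = seq[i : i + L]
            if not _oracle_clean(window):
                continue
            # plus-strand window vs reverse-complemented query; mismatch at
            # plus index k is protospacer position L - k (1-based from 5')
            mism = tuple(
                sorted(L - k for k in range(L) if window[k] != rc_query[k])
            )
            if len(mism) <= query.max_mismatches:
                hits.add((chrom, i, i + L, "-", mism))
    return hits


# --- fixture specification ---------------------------------------------------

_MOTIF_WORDS = ("AATAAA", "ATTAAA", "TTTATT", "TTTAAT")  # both strands


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic test genome."""

    length: int = 50_000
    seed: int = 0
    chrom: str = "fx1"
    n_coding_editable: int = 10
    n_template_editable: int = 5
    n_no_pam_decoy: int = 5
    n_wrong_gap_decoy: int = 3
    n_pseudo_motif: int = 2
    n_other_motif: int = 0
    other_hexamer: str = "AGTAAA"
    #: each entry = 1-based mismatch positions of one planted near-match
    #: locus; an empty tuple plants an exact (on-target) copy.
    offtarget_plants: tuple[tuple[int, ...], ...] = ()
    protospacer: str | None = None
    pam: str = "NGG"
    max_mismatches: int = 4
    motifs: tuple[str, ...] = ("AATAAA", "ATTAAA")
    background: str = "uniform"  # or "at_rich"

    @property
    def n_motif_plants(self) -> int:
        return (
            self.n_coding_editable
            + self.n_template_editable
            + self.n_no_pam_decoy
            + self.n_wrong_gap_decoy
        )

    @property
    def n_plants(self) -> int:
        return (
            self.n_motif_plants
            + self.n_pseudo_motif
            + self.n_other_motif
            + len(self.offtarget_plants)
        )


@dataclass(frozen=True)
class PlantedFeature:
    """One planted feature with its by-construction truth."""

    category: str
    chrom: str
    start: int  # hexamer span for motif plants, protospacer span otherwise
    end: int
    strand: str
    hexamer: str | None = None
    expected_editable: bool | None = None
    expected_guide_count: int | None = None
    expected_mismatch_positions: tuple[int, ...] | None = None
    expected_criteria: tuple[bool, bool, bool] | None = None

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TruthManifest:
    features: tuple[PlantedFeature, ...]
    protospacer: str | None
    pam: str

    def by_category(self, *categories: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.category in categories]


class FixtureError(RuntimeError):
    pass


# --- payload construction ----------------------------------------------------

def _creates_motif(tail: str) -> bool:
    return len(tail) >= 6 and tail[-6:] in _MOTIF_WORDS


def _sample_bases(rng, n: int, context: str, no_gg_cc: bool) -> str:
    """Sample n bases avoiding canonical-motif creation (and, when asked,
    GG/CC dinucleotides) given the preceding context."""
    out: list[str] = []
    tail = context[-5:]
    for _ in range(n):
        for _attempt in range(100):
            b = "ACGT"[int(rng.integers(4))]
            if no_gg_cc and tail and tail[-1] == b and b in "GC":
                continue
            if _creates_motif(tail + b):
                continue
            break
        else:
            raise FixtureError("could not sample a guard base")
        out.append(b)
        tail = (tail + b)[-5:]
    return "".join(out)


def _payload_motif_count(payload: str, expected_word: str | None) -> bool:
    """True iff the payload contains exactly the expected planted hexamer
    occurrence and no other canonical-motif word on either strand."""
    total = 0
    expected_hits = 0
    for word in _MOTIF_WORDS:
        start = payload.find(word)
        while start != -1:
            total += 1
            if word == expected_word:
                expected_hits += 1
            start = payload.find(word, start + 1)
    if expected_word is None:
        return total == 0
    return total == 1 and expected_hits == 1


def _build_payload(rng, builder, expected_word, tries: int = 100) -> tuple[str, tuple[int, int]]:
    for _ in range(tries):
        payload, span = builder(rng)
        if _payload_motif_count(payload, expected_word):
            return payload, span
    raise FixtureError("payload construction kept producing stray motifs")


def _coding_editable(rng, hexamer: str):
    def build(rng):
        g = int(rng.integers(10, 17))
        gap = _sample_bases(rng, g, hexamer, no_gg_cc=False)
        n_base = "ACGT"[int(rng.integers(4))]
        return hexamer + gap + n_base + "GG", (0, 6)

    return build


def _template_editable(rng, hexamer: str):
    def build(rng):
        g = int(rng.integers(10, 15))
        n_base = "ACGT"[int(rng.integers(4))]
        gap = _sample_bases(rng, g, "CC" + n_base, no_gg_cc=False)
        return "CC" + n_base + gap + hexamer, (3 + g, 9 + g)

    return build


def _no_pam_decoy(rng, hexamer: str):
    def build(rng):
        left = _sample_bases(rng, 17, "", no_gg_cc=True)
        right = _sample_bases(rng, 19, left + hexamer, no_gg_cc=True)
        return left + hexamer + right, (17, 23)

    return build


def _wrong_gap_decoy(rng, hexamer: str):
    def build(rng):
        left = _sample_bases(rng, 17, "", no_gg_cc=True)
        right = list(_sample_bases(rng, 22, left + hexamer, no_gg_cc=True))
        # the only GG sits at gap 18 (hexamer-end offsets 19-20), outside
        # the editable gap range; neighbours forced non-G to keep it alone
        right[19] = right[20] = "G"
        if right[18] == "G":
            right[18] = "A"
        if right[21] == "G":
            right[21] = "T"
        return left + hexamer + "".join(right), (17, 23)

    return build


def _bystander_hexamer(rng, hexamer: str):
    def build(rng):
        gap = _sample_bases(rng, 14, hexamer, no_gg_cc=False)
        n_base = "ACGT"[int(rng.integers(4))]
        return hexamer + gap + n_base + "GG", (0, 6)

    return build


def _offtarget_payload(rng, protospacer: str, mm_positions: tuple[int, ...]):
    def build(rng):
        variant = list(protospacer)
        for p in mm_positions:
            alternatives = [b for b in "ACGT" if b != protospacer[p - 1]]
            variant[p - 1] = alternatives[int(rng.integers(3))]
        n_base = "ACGT"[int(rng.integers(4))]
        return "".join(variant) + n_base + "GG", (0, len(protospacer))

    return build


# --- generation --------------------------------------------------------------

def _random_protospacer(rng, length: int = 20) -> str:
    for _ in range(100):
        p = "".join("ACGT"[int(rng.integers(4))] for _ in range(length))
        if _payload_motif_count(p, None):
            return p
    raise FixtureError("could not draw a motif-free protospacer")


def _hamming_near(word: str, ref: str, limit: int) -> tuple[int, ...] | None:
    mism = []
    for k, (a, b) in enumerate(zip(word, ref)):
        if a != b:
            mism.append(k + 1)
            if len(mism) > limit:
                return None
    return tuple(mism)


def generate(spec: FixtureSpec, max_attempts: int = 8) -> tuple[dict[str, str], TruthManifest]:
    """Build the fixture genome and its truth manifest.

    Identical specs produce byte-identical genomes.  Raises
    :class:`FixtureError` on infeasible packing or when the scrub/oracle
    gate cannot be satisfied within the retry budget.
    """
    m = spec.n_plants
    if m == 0:
        raise FixtureError("fixture spec plants nothing")
    block = spec.length // m
    if block < 150:
        raise FixtureError(
            f"infeasible packing: {m} plants need >= {m * 150} bp, genome is {spec.length}"
        )
    last_error = "unknown"
    for attempt in range(max_attempts):
        rng = np.random.default_rng((spec.seed + 1_000_003 * attempt) % 2**31)
        try:
            return _generate_once(spec, rng, block)
        except FixtureError as exc:
            last_error = str(exc)
    raise FixtureError(
        f"fixture generation failed after {max_attempts} attempts: {last_error}; "
        "try a longer genome or another seed"
    )


def _generate_once(spec: FixtureSpec, rng, block: int) -> tuple[dict[str, str], TruthManifest]:
    if spec.background == "at_rich":
        probs = [0.35, 0.15, 0.15, 0.35]
    else:
        probs = [0.25, 0.25, 0.25, 0.25]
    genome = ["ACGT"[i] for i in rng.choice(4, size=spec.length, p=probs)]
    protected = np.zeros(spec.length, dtype=bool)

    protospacer = spec.protospacer
    if spec.offtarget_plants and protospacer is None:
        protospacer = _random_protospacer(rng)
    query = (
        OffTargetQuery(protospacer, pam=spec.pam, max_mismatches=spec.max_mismatches)
        if protospacer is not None and spec.offtarget_plants
        else None
    )

    # --- build payloads -----------------------------------------------------
    plan: list[tuple[str, str, tuple[int, int], dict]] = []  # (category, payload, hex_span, extra)
    motif_cycle = [spec.motifs[i % len(spec.motifs)] for i in range(spec.n_motif_plants)]
    idx = 0
    for _ in range(spec.n_coding_editable):
        hx = motif_cycle[idx]; idx += 1
        payload, span = _build_payload(rng, _coding_editable(rng, hx), hx)
        plan.append(("coding_editable", payload, span, {"hexamer": hx, "editable": True}))
    for _ in range(spec.n_template_editable):
        hx = motif_cycle[idx]; idx += 1
        payload, span = _build_payload(rng, _template_editable(rng, hx), hx)
        plan.append(("template_editable", payload, span, {"hexamer": hx, "editable": True}))
    for _ in range(spec.n_no_pam_decoy):
        hx = motif_cycle[idx]; idx += 1
        payload, span = _build_payload(rng, _no_pam_decoy(rng, hx), hx)
        plan.append(("no_pam_decoy", payload, span, {"hexamer": hx, "editable": False}))
    for _ in range(spec.n_wrong_gap_decoy):
        hx = motif_cycle[idx]; idx += 1
        payload, span = _build_payload(rng, _wrong_gap_decoy(rng, hx), hx)
        plan.append(("wrong_gap_decoy", payload, span, {"hexamer": hx, "editable": False}))
    for _ in range(spec.n_pseudo_motif):
        payload, span = _build_payload(rng, _bystander_hexamer(rng, "ATCAAA"), None)
        plan.append(("pseudo_motif", payload, span, {"hexamer": "ATCAAA", "editable": None}))
    for _ in range(spec.n_other_motif):
        payload, span = _build_payload(rng, _bystander_hexamer(rng, spec.other_hexamer), None)
        plan.append(("other_motif", payload, span, {"hexamer": spec.other_hexamer, "editable": None}))
    for mm in spec.offtarget_plants:
        if len(mm) > spec.max_mismatches:
            raise FixtureError(f"off-target plant {mm} exceeds max_mismatches={spec.max_mismatches}")
        payload, span = _build_payload(rng, _offtarget_payload(rng, protospacer, mm), None)
        plan.append(("offtarget", payload, span, {"mm": mm}))

    # --- place payloads, random strand, one per block ------------------------
    features: list[PlantedFeature] = []
    ot_payload_seqs: list[str] = []  # protospacer+PAM as read on guide strand
    for j, (category, payload, span, extra) in enumerate(plan):
        strand = "+" if int(rng.integers(2)) == 0 else "-"
        plen = len(payload)
        lo_off = 20
        hi_off = block - plen - 20
        offset = int(rng.integers(lo_off, hi_off + 1))
        start = j * block + offset
        if strand == "+":
            inserted = payload
            fstart, fend = start + span[0], start + span[1]
        else:
            inserted = _oracle_revcomp(payload)
            fstart, fend = start + plen - span[1], start + plen - span[0]
        genome[start : start + plen] = list(inserted)
        protected[start : start + plen] = True
        if category == "offtarget":
            ot_payload_seqs.append(payload[: len(protospacer) + len(spec.pam)])
            features.append(
                PlantedFeature(
                    category, spec.chrom, fstart, fend, strand,
                    expected_mismatch_positions=tuple(extra["mm"]),
                )
            )
        else:
            features.append(
                PlantedFeature(
                    category, spec.chrom, fstart, fend, strand,
                    hexamer=extra["hexamer"], expected_editable=extra["editable"],
                )
            )

    # --- scrub background ----------------------------------------------------
    _scrub(genome, protected, rng, features, query)
    seq = "".join(genome)

    # --- self-consistency gate ----------------------------------------------
    editor = EditorSpec("spcas9-abemax", pam="NGG")
    motif_specs = tuple(PASMotifSpec(h) for h in spec.motifs)
    site_guides = oracle_site_guides({spec.chrom: seq}, editor, motif_specs)
    motif_feats = [f for f in features if f.category.endswith(("editable", "decoy"))]
    planted_keys = {f.key for f in motif_feats}
    if set(site_guides) != planted_keys:
        raise FixtureError("oracle motif-site set differs from planting manifest")
    expected_editable = {f.key for f in motif_feats if f.expected_editable}
    oracle_editable = {k for k, n in site_guides.items() if n > 0}
    if oracle_editable != expected_editable:
        raise FixtureError("oracle editability differs from planting manifest")

    if query is not None:
        ot_feats = [f for f in features if f.category == "offtarget"]
        expected_ot = {
            (f.chrom, f.start, f.end, f.strand, f.expected_mismatch_positions)
            for f in ot_feats
        }
        if oracle_near_matches({spec.chrom: seq}, query) != expected_ot:
            raise FixtureError("oracle near-match set differs from planting manifest")
        # expected filter verdicts, by construction
        L = len(protospacer)
        seed_start = L - query.seed_len + 1
        win_lo, win_hi = editor.window
        counts = {s: ot_payload_seqs.count(s) for s in ot_payload_seqs}
        annotated = []
        for f, payload_seq in zip(ot_feats, ot_payload_seqs):
            mm = f.expected_mismatch_positions
            c1 = all(p < seed_start for p in mm) and len(mm) <= 4
            c2 = any(payload_seq[w - 1] == editor.source_base for w in range(win_lo, win_hi + 1))
            c3 = counts[payload_seq] == 1
            annotated.append(
                PlantedFeature(
                    f.category, f.chrom, f.start, f.end, f.strand,
                    expected_mismatch_positions=mm, expected_criteria=(c1, c2, c3),
                )
            )
        features = [f for f in features if f.category != "offtarget"] + annotated

    # attach oracle guide counts to motif plants
    final = []
    for f in features:
        if f.key in site_guides:
            final.append(
                PlantedFeature(
                    f.category, f.chrom, f.start, f.end, f.strand,
                    hexamer=f.hexamer, expected_editable=f.expected_editable,
                    expected_guide_count=site_guides[f.key],
                )
            )
        else:
            final.append(f)
    final.sort(key=lambda f: (f.start, f.end))
    manifest = TruthManifest(tuple(final), protospacer, spec.pam)
    return {spec.chrom: seq}, manifest


def _scrub(genome, protected, rng, features, query, max_rounds: int = 80) -> None:
    """Resample background bases until no accidental canonical-motif word
    or near-match to the off-target query survives outside the plants."""
    planted_words = {}
    for f in features:
        if f.hexamer in (None,) or not f.category.endswith(("editable", "decoy")):
            continue
        word = f.hexamer if f.strand == "+" else _oracle_revcomp(f.hexamer)
        planted_words[f.start] = word
    planted_ot = {
        (f.start, f.end, f.strand): f
        for f in features
        if f.category == "offtarget"
    }
    for _ in range(max_rounds):
        seq = "".join(genome)
        dirty: set[int] = set()
        for word in _MOTIF_WORDS:
            start = seq.find(word)
            while start != -1:
                if planted_words.get(start) != word:
                    span = [i for i in range(start, start + 6) if not protected[i]]
                    if not span:
                        raise FixtureError("stray motif wholly inside a protected plant")
                    dirty.update(span)
                start = seq.find(word, start + 1)
        if query is not None:
            dirty.update(_near_match_dirt(seq, protected, query, planted_ot))
        if not dirty:
            return
        for i in dirty:
            genome[i] = "ACGT"[int(rng.integers(4))]
    raise FixtureError("scrub budget exceeded; genome too short for rejection sampling")


def _near_match_dirt(seq, protected, query, planted_ot) -> set[int]:
    L = len(query.protospacer)
    npam = len(query.pam)
    dirty: set[int] = set()
    rc_query = _oracle_revcomp(query.protospacer)
    n = len(seq)
    for i in range(n - L - npam + 1):
        pam = seq[i + L : i + L + npam]
        if _oracle_pam_ok(pam, query.pam):
            if _hamming_near(seq[i : i + L], query.protospacer, query.max_mismatches) is not None:
                if (i, i + L, "+") not in planted_ot:
                    span = [k for k in range(i, i + L + npam) if not protected[k]]
                    if not span:
                        raise FixtureError("stray near-match wholly inside a protected plant")
                    dirty.update(span)
    rc_pam = _oracle_revcomp(query.pam)
    for i in range(npam, n - L + 1):
        pam_plus = seq[i - npam : i]
        ok = all(b in "ACGT" and b in _ORACLE_IUPAC[sym] for b, sym in zip(pam_plus, rc_pam))
        if ok and _hamming_near(seq[i : i + L], rc_query, query.max_mismatches) is not None:
            if (i, i + L, "-") not in planted_ot:
                span = [k for k in range(i - npam, i + L) if not protected[k]]
                if not span:
                    raise FixtureError("stray near-match wholly inside a protected plant")
                dirty.update(span)
    return dirty


# --- emission ----------------------------------------------------------------

def write_fixture(
    genome: Mapping[str, str], manifest: TruthManifest, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.fa``, ``<prefix>.truth.tsv`` and ``<prefix>.bed``."""
    prefix = Path(prefix)
    fa = prefix.with_suffix(".fa")
    with open(fa, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    rows = []
    for f in manifest.features:
        rows.append(
            {
                "category": f.category,
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "hexamer": f.hexamer or "",
                "expected_editable": "" if f.expected_editable is None else int(f.expected_editable),
                "expected_guide_count": "" if f.expected_guide_count is None else f.expected_guide_count,
                "expected_mismatch_positions": ",".join(
                    map(str, f.expected_mismatch_positions or ())
                ),
                "expected_criteria": ",".join(
                    str(int(c)) for c in (f.expected_criteria or ())
                ),
            }
        )
    truth = Path(f"{prefix}.truth.tsv")
    pd.DataFrame(rows).to_csv(truth, sep="\t", index=False)
    bed = prefix.with_suffix(".bed")
    with open(bed, "w") as fh:
        for f in manifest.features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.category}\t0\t{f.strand}\n"
            )
    return fa, truth, bed
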