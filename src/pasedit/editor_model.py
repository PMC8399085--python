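"""Base-editor and PAS-motif specifications plus placement geometry.

The central question this module answers is purely geometric: given a base
that a base editor could chemically convert (an adenine, for the A->G
editors), does a protospacer placement exist such that

* the base falls inside the editor's activity window (1-based positions
  counted from the protospacer 5', PAM-distal end), and
* the PAM, read on the protospacer strand immediately 3' of the
  protospacer, matches the editor's IUPAC PAM pattern?

For a polyadenylation-signal hexamer the disruptable bases come in two
flavours.  "Coding" disruption edits an adenine of the hexamer itself
(for AATAAA/ATTAAA: the last three positions), with the guide on the same
strand as the hexamer.  "Template" disruption edits the adenine on the
opposite strand that pairs with a hexamer thymine (the middle T, hexamer
position 3), with the guide on the opposite strand; on the coding strand
the outcome reads as T->C (ATTAAA -> ATCAAA, the naturally non-functional
chromosome-10 variant of the DUX4 PAS).

All genomic coordinates are 0-based half-open on the plus strand; window
and hexamer positions are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping

import yaml

from ._seq import DNA, IUPAC_BASES, complement_base, is_unambiguous, matches_iupac, revcomp

StrandMode = Literal["coding", "template"]
STRAND_MODES: tuple[StrandMode, StrandMode] = ("coding", "template")


@dataclass(frozen=True)
class EditorSpec:
    """Targeting rules of a Cas9-coupled base editor.

    Parameters
    ----------
    name:
        Free-text label, e.g. ``spcas9-abemax``.
    pam:
        IUPAC PAM pattern matched immediately 3' of the protospacer on the
        protospacer strand (``NGG`` for SpCas9).
    protospacer_len:
        Protospacer length in nt (20 for SpCas9 guides).
    window:
        Inclusive 1-based activity-window bounds counted from the
        protospacer 5' (PAM-distal) end; ``(4, 8)`` for ABEmax.
    conversion:
        ``(source, product)`` base pair; adenine base editors convert A->G.
    """

    name: str
    pam: str = "NGG"
    protospacer_len: int = 20
    window: tuple[int, int] = (4, 8)
    conversion: tuple[str, str] = ("A", "G")

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.protospacer_len):
            raise ValueError(f"window {self.window} must satisfy 1 <= lo <= hi <= protospacer_len")
        if not self.pam or any(sym not in IUPAC_BASES for sym in self.pam):
            raise ValueError(f"PAM {self.pam!r} must be a non-empty IUPAC DNA pattern")
        src, prod = self.conversion
        if src == prod or src not in DNA or prod not in DNA:
            raise ValueError(f"conversion {self.conversion} must be two distinct ACGT bases")

    @property
    def source_base(self) -> str:
        return self.conversion[0]

    @property
    def product_base(self) -> str:
        return self.conversion[1]


@dataclass(frozen=True)
class PASMotifSpec:
    """A PAS hexamer with its disruptable positions.

    ``coding_disruptable`` positions carry the editor's source base on the
    hexamer (coding) strand; ``template_disruptable`` positions carry its
    complement, so the editable base sits on the opposite strand.
    """

    hexamer: str
    coding_disruptable: frozenset[int] = frozenset({4, 5, 6})
    template_disruptable: frozenset[int] = frozenset({3})
    source_base: str = "A"

    def __post_init__(self) -> None:
        if len(self.hexamer) != 6 or not is_unambiguous(self.hexamer):
            raise ValueError(f"hexamer {self.hexamer!r} must be 6 nt over ACGT")
        object.__setattr__(self, "coding_disruptable", frozenset(self.coding_disruptable))
        object.__setattr__(self, "template_disruptable", frozenset(self.template_disruptable))
        comp = complement_base(self.source_base)
        for pos in self.coding_disruptable:
            if not 1 <= pos <= 6 or self.hexamer[pos - 1] != self.source_base:
                raise ValueError(
                    f"coding position {pos} of {self.hexamer} does not carry {self.source_base}"
                )
        for pos in self.template_disruptable:
            if not 1 <= pos <= 6 or self.hexamer[pos - 1] != comp:
                raise ValueError(
                    f"template position {pos} of {self.hexamer} does not carry {comp}"
                )

    def disruptable(self, strand_mode: StrandMode) -> frozenset[int]:
        if strand_mode == "coding":
            return self.coding_disruptable
        if strand_mode == "template":
            return self.template_disruptable
        raise ValueError(f"unknown strand_mode {strand_mode!r}")


#: The two canonical PAS hexamers with the default disruption rules:
#: coding-strand adenines at the last three positions, template-strand
#: adenine paired with the middle thymine (position 3).
DEFAULT_MOTIFS: tuple[PASMotifSpec, PASMotifSpec] = (
    PASMotifSpec("AATAAA"),
    PASMotifSpec("ATTAAA"),
)


def default_motifs() -> tuple[PASMotifSpec, ...]:
    return DEFAULT_MOTIFS


def motif_specs(hexamers: Iterable[str]) -> tuple[PASMotifSpec, ...]:
    """Motif specs for hexamer strings; defaults only fit AATAAA/ATTAAA."""
    by_hex = {m.hexamer: m for m in DEFAULT_MOTIFS}
    out = []
    for hx in hexamers:
        hx = hx.upper()
        if hx not in by_hex:
            raise ValueError(
                f"no default disruption rule for {hx}; construct a PASMotifSpec explicitly"
            )
        out.append(by_hex[hx])
    return tuple(out)


@dataclass(frozen=True)
class GuidePlacement:
    """One protospacer placement that puts an editable base in the window.

    Intervals are 0-based half-open on the plus strand; ``window_pos`` is
    the 1-based protospacer position of the edited base.  On a minus-strand
    guide the protospacer 5' end corresponds to the *right* edge of
    ``protospacer_interval`` and the PAM lies to its left on the plus
    strand.
    """

    target_genomic_pos: int
    guide_strand: str
    window_pos: int
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]


def load_presets() -> dict[str, EditorSpec]:
    """Editor presets shipped with the package (``spcas9-abemax`` etc.)."""
    text = resources.files("pasedit").joinpath("data/editors.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, cfg in raw.items():
        out[name] = EditorSpec(
            name=name,
            pam=cfg["pam"],
            protospacer_len=cfg["protospacer_len"],
            window=(cfg["window"][0], cfg["window"][1]),
            conversion=(cfg["conversion"][0], cfg["conversion"][1]),
        )
    return out


def get_editor(name: str) -> EditorSpec:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown editor preset {name!r}; available: {sorted(presets)}") from None


def placements_for_target(
    target_pos: int,
    target_strand: str,
    editor: EditorSpec,
    seq: str,
) -> list[GuidePlacement]:
    """All protospacer placements editing the base at ``target_pos``.

    ``target_strand`` is the strand carrying the editor's source base; the
    guide always lies on that same strand, because base editors act on the
    protospacer-strand base displaced by the sgRNA:DNA heteroduplex.

    Raises ``ValueError`` when the position is out of range or the strand
    base is a concrete ACGT base different from the source base.  An
    ambiguous reference base (e.g. N) is unscannable: a warning is issued
    and no placement is returned.
    """
    if target_strand not in "+-" or len(target_strand) != 1:
        raise ValueError(f"target_strand must be '+' or '-', got {target_strand!r}")
    if not 0 <= target_pos < len(seq):
        raise ValueError(f"target_pos {target_pos} outside sequence of length {len(seq)}")
    base = seq[target_pos].upper()
    strand_base = base if target_strand == "+" else complement_base(base)
    if strand_base not in DNA:
        warnings.warn(
            f"ambiguous base {base!r} at position {target_pos}: unscannable, no placements",
            stacklevel=2,
        )
        return []
    if strand_base != editor.source_base:
        raise ValueError(
            f"base at {target_pos} on strand {target_strand} is {strand_base}, "
            f"not the editor source base {editor.source_base}"
        )

    length = len(seq)
    plen = editor.protospacer_len
    npam = len(editor.pam)
    lo, hi = editor.window
    placements: list[GuidePlacement] = []
    for w in range(lo, hi + 1):
        if target_strand == "+":
            start = target_pos - (w - 1)
            proto = (start, start + plen)
            pam = (start + plen, start + plen + npam)
            if proto[0] < 0 or pam[1] > length:
                continue
            pam_seq = seq[pam[0] : pam[1]].upper()
        else:
            start = target_pos - plen + w
            proto = (start, start + plen)
            pam = (start - npam, start)
            if pam[0] < 0 or proto[1] > length:
                continue
            pam_seq = revcomp(seq[pam[0] : pam[1]].upper())
        proto_seq = seq[proto[0] : proto[1]].upper()
        if not is_unambiguous(proto_seq):
            continue
        if not matches_iupac(pam_seq, editor.pam):
            continue
        placements.append(
            GuidePlacement(
                target_genomic_pos=target_pos,
                guide_strand=target_strand,
                window_pos=w,
                protospacer_interval=proto,
                pam_interval=pam,
            )
        )
    return placements


def gap_range(
    editor: EditorSpec, motif: PASMotifSpec, strand_mode: StrandMode
) -> tuple[int, int]:
    """Inclusive range of hexamer-to-PAM gaps admitting a valid guide.

    For ``coding`` mode the gap runs from the hexamer 3' end to the PAM
    start (both on the hexamer strand); for ``template`` mode, viewing the
    reverse-strand guide on the plus strand, from the PAM end to the
    hexamer 5' start.  With protospacer length L, disruptable position p
    and window position w the gap is ``p - w + L - 6`` (coding) or
    ``L + 1 - p - w`` (template); the range is taken over all valid
    (p, w) combinations.
    """
    positions = motif.disruptable(strand_mode)
    if not positions:
        raise ValueError(f"motif {motif.hexamer} has no {strand_mode}-disruptable positions")
    L = editor.protospacer_len
    lo, hi = editor.window
    gaps = []
    for p in positions:
        for w in range(lo, hi + 1):
            if strand_mode == "coding":
                gaps.append(p - w + L - 6)
            else:
                gaps.append(L + 1 - p - w)
    return (min(gaps), max(gaps))


def predicted_edited_hexamer(
    motif: PASMotifSpec, position: int, strand_mode: StrandMode, editor: EditorSpec | None = None
) -> str:
    """Hexamer sequence (coding strand) after editing ``position``.

    Coding mode substitutes source -> product directly; template mode
    substitutes the coding base with the complement of the product base
    (A->G on the template strand reads T->C on the coding strand).
    """
    src = "A" if editor is None else editor.source_base
    prod = "G" if editor is None else editor.product_base
    if position not in motif.disruptable(strand_mode):
        raise ValueError(
            f"position {position} of {motif.hexamer} is not {strand_mode}-disruptable"
        )
    bases = list(motif.hexamer)
    if strand_mode == "coding":
        bases[position - 1] = prod
    else:
        bases[position - 1] = complement_base(prod)
    return "".join(bases)


# --- site-level guide enumeration -------------------------------------------

@dataclass(frozen=True)
class MotifSite:
    """A genomic occurrence of a PAS hexamer.

    ``interval`` is the 0-based half-open hexamer span on the plus strand;
    ``hexamer`` is the motif as read on ``strand``.
    """

    chrom: str
    interval: tuple[int, int]
    strand: str
    hexamer: str

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.interval[0], self.interval[1], self.strand)


@dataclass(frozen=True)
class GuideCandidate:
    """One sgRNA (protospacer + PAM placement) disrupting a PAS site.

    A single placement whose window spans several disruptable hexamer
    positions is one candidate listing them all (``captured_positions``
    maps 1-based hexamer position -> window position), not several
    duplicate candidates.
    """

    placement: GuidePlacement
    strand_mode: StrandMode
    protospacer_seq: str
    pam_seq: str
    captured_positions: tuple[tuple[int, int], ...]
    predicted_hexamers: frozenset[str]

    @property
    def hexamer_positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.captured_positions)


def _hexamer_pos_to_plus_coord(site: MotifSite, position: int) -> int:
    start, end = site.interval
    if site.strand == "+":
        return start + position - 1
    return end - position


def enumerate_guides_for_site(
    site: MotifSite,
    editor: EditorSpec,
    motif: PASMotifSpec,
    seq: str,
) -> list[GuideCandidate]:
    """Every guide that disrupts ``site``, across both strand modes.

    The site is editable iff the returned list is non-empty.  Placements
    sharing a protospacer interval and strand are merged into a single
    candidate whose ``captured_positions`` lists each disruptable hexamer
    position the window reaches.
    """
    if site.hexamer != motif.hexamer:
        raise ValueError(
            f"hexamer-mismatch: site carries {site.hexamer}, motif spec is {motif.hexamer}"
        )
    grouped: dict[tuple[str, tuple[int, int], StrandMode], dict] = {}
    for mode in STRAND_MODES:
        if mode == "coding":
            target_strand = site.strand
        else:
            target_strand = "-" if site.strand == "+" else "+"
        for p in sorted(motif.disruptable(mode)):
            coord = _hexamer_pos_to_plus_coord(site, p)
            for pl in placements_for_target(coord, target_strand, editor, seq):
                key = (pl.guide_strand, pl.protospacer_interval, mode)
                entry = grouped.setdefault(
                    key, {"placement": pl, "captured": [], "mutants": set()}
                )
                entry["captured"].append((p, pl.window_pos))
                entry["mutants"].add(predicted_edited_hexamer(motif, p, mode, editor))

    candidates = []
    for (strand, proto, mode), entry in sorted(grouped.items()):
        proto_seq = seq[proto[0] : proto[1]].upper()
        pam = entry["placement"].pam_interval
        pam_seq = seq[pam[0] : pam[1]].upper()
        if strand == "-":
            proto_seq = revcomp(proto_seq)
            pam_seq = revcomp(pam_seq)
        candidates.append(
            GuideCandidate(
                placement=entry["placement"],
                strand_mode=mode,
                protospacer_seq=proto_seq,
                pam_seq=pam_seq,
                captured_positions=tuple(sorted(entry["captured"])),
                predicted_hexamers=frozenset(entry["mutants"]),
            )
        )
    return candidates
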