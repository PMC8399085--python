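"""Genome-wide discovery of editable polyadenylation signals.

Two interchangeable engines decide, for every occurrence of a PAS hexamer
on either strand, whether at least one base-editor guide can disrupt it:

* ``direct`` — positional enumeration through
  :func:`pasedit.editor_model.enumerate_guides_for_site`; yields the full
  guide list per site.
* ``regex`` — the regular-expression construction: the hexamer, a bounded
  gap, and the PAM collapsed into one plus-strand pattern per strand mode
  (reverse-strand occurrences are found by scanning the reverse
  complement).  Decides editability only; the guide list stays empty.

Regex matching is overlap-tolerant (the search restarts one base after
each match start) so that nearby motif occurrences sharing context are
never masked by a greedy gap quantifier.  Each anchored match is confirmed
against sequence bounds and ambiguity codes before a site is flagged, so
both engines agree exactly, including at sequence ends.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from ._seq import is_unambiguous, iupac_char_class, matches_iupac, revcomp
from .editor_model import (
    EditorSpec,
    GuideCandidate,
    MotifSite,
    PASMotifSpec,
    STRAND_MODES,
    StrandMode,
    enumerate_guides_for_site,
    gap_range,
)

logger = logging.getLogger(__name__)

GUIDE_TSV_COLUMNS = [
    "chrom",
    "site_start",
    "site_end",
    "site_strand",
    "motif",
    "guide_strand",
    "strand_mode",
    "protospacer",
    "pam",
    "protospacer_start",
    "protospacer_end",
    "window_positions",
    "captured_positions",
    "predicted_hexamers",
]


@dataclass(frozen=True)
class EditablePASRecord:
    """One PAS occurrence with its editability verdict and guides."""

    site: MotifSite
    guides: tuple[GuideCandidate, ...]
    editable: bool

    def __post_init__(self) -> None:
        if self.guides and not self.editable:
            raise ValueError("a record with guides must be editable")


def find_motif_sites(
    seq: str, motifs: Sequence[PASMotifSpec], chrom: str = "seq"
) -> list[MotifSite]:
    """All occurrences of each motif on both strands, overlaps included.

    Reverse-strand occurrences are reported with their plus-strand
    interval and ``strand='-'``; ``hexamer`` is always the motif as read
    on its own strand.
    """
    s = seq.upper()
    sites: list[MotifSite] = []
    for motif in motifs:
        for strand, needle in (("+", motif.hexamer), ("-", revcomp(motif.hexamer))):
            start = s.find(needle)
            while start != -1:
                sites.append(MotifSite(chrom, (start, start + 6), strand, motif.hexamer))
                start = s.find(needle, start + 1)
    sites.sort(key=lambda m: (m.interval, m.strand, m.hexamer))
    return sites


def build_editable_regex(
    editor: EditorSpec, motif: PASMotifSpec, strand_mode: StrandMode
) -> str:
    """Plus-strand pattern whose match-existence at a hexamer means
    "at least one valid guide exists in ``strand_mode``".

    Coding mode: ``HEXAMER [ACGT]{lo,hi} PAM``.  Template mode is the
    plus-strand mirror of the reverse-strand guide:
    ``revcomp(PAM) [ACGT]{lo,hi} HEXAMER``.  The gap bounds come from
    :func:`pasedit.editor_model.gap_range`; only explicit character
    classes are used.
    """
    lo, hi = gap_range(editor, motif, strand_mode)
    if lo < 0:
        raise ValueError(
            f"no geometric solution: gap range [{lo}, {hi}] extends below zero "
            f"for {motif.hexamer} in {strand_mode} mode"
        )
    gap = f"[ACGT]{{{lo},{hi}}}"
    pam_fwd = "".join(iupac_char_class(sym) for sym in editor.pam)
    pam_rev = "".join(iupac_char_class(sym) for sym in revcomp(editor.pam))
    if strand_mode == "coding":
        return f"{motif.hexamer}(?P<gap>{gap}){pam_fwd}"
    return f"{pam_rev}(?P<gap>{gap}){motif.hexamer}"


def _verify_anchor(
    seq: str, h: int, editor: EditorSpec, lo: int, hi: int, strand_mode: StrandMode
) -> bool:
    """Confirm a regex anchor: some in-range gap yields an in-bounds,
    ambiguity-free protospacer + PAM.  Needed because a match can imply a
    protospacer extending past the sequence edge or across an N outside
    the matched span."""
    L = editor.protospacer_len
    npam = len(editor.pam)
    n = len(seq)
    for g in range(lo, hi + 1):
        if strand_mode == "coding":
            pam_start = h + 6 + g
            proto = (pam_start - L, pam_start)
            pam = (pam_start, pam_start + npam)
            if proto[0] < 0 or pam[1] > n:
                continue
            pam_seq = seq[pam[0] : pam[1]]
        else:
            pam_end = h - g
            proto = (pam_end, pam_end + L)
            pam = (pam_end - npam, pam_end)
            if pam[0] < 0 or proto[1] > n:
                continue
            pam_seq = revcomp(seq[pam[0] : pam[1]])
        if not matches_iupac(pam_seq, editor.pam):
            continue
        if is_unambiguous(seq[proto[0] : proto[1]]):
            return True
    return False


def _regex_editable_hexamer_starts(
    seq: str, editor: EditorSpec, motif: PASMotifSpec, strand_mode: StrandMode
) -> set[int]:
    """Start positions (in ``seq``) of hexamers flagged editable by the
    regex engine for one strand mode."""
    try:
        pattern = build_editable_regex(editor, motif, strand_mode)
    except ValueError:
        return set()
    lo, hi = gap_range(editor, motif, strand_mode)
    rx = re.compile(pattern)
    npam = len(editor.pam)
    found: set[int] = set()
    pos = 0
    while (m := rx.search(seq, pos)) is not None:
        if strand_mode == "coding":
            # the hexamer is the match start; every start is enumerated
            candidates = [m.start()]
        else:
            # the hexamer sits at the match end and one PAM anchor can
            # reach several hexamers, of which the greedy gap reports only
            # one - enumerate every in-range offset from the anchor
            candidates = [
                h
                for g in range(lo, hi + 1)
                if seq[(h := m.start() + npam + g) : h + 6] == motif.hexamer
            ]
        for h in candidates:
            if h not in found and _verify_anchor(seq, h, editor, lo, hi, strand_mode):
                found.add(h)
        pos = m.start() + 1  # overlap-tolerant restart
    return found


def _scan_sequence(
    chrom: str,
    seq: str,
    editor: EditorSpec,
    motifs: Sequence[PASMotifSpec],
    engine: str,
) -> list[EditablePASRecord]:
    s = seq.upper()
    sites = find_motif_sites(s, motifs, chrom=chrom)
    by_hex = {m.hexamer: m for m in motifs}
    records: list[EditablePASRecord] = []
    if engine == "direct":
        for site in sites:
            guides = enumerate_guides_for_site(site, editor, by_hex[site.hexamer], s)
            records.append(EditablePASRecord(site, tuple(guides), bool(guides)))
    elif engine == "regex":
        n = len(s)
        rc = revcomp(s)
        editable_plus: dict[str, set[int]] = {}
        editable_minus: dict[str, set[int]] = {}
        for motif in motifs:
            plus: set[int] = set()
            minus_rc: set[int] = set()
            for mode in STRAND_MODES:
                plus |= _regex_editable_hexamer_starts(s, editor, motif, mode)
                minus_rc |= _regex_editable_hexamer_starts(rc, editor, motif, mode)
            editable_plus[motif.hexamer] = plus
            # mirror reverse-complement coordinates back to the plus strand
            editable_minus[motif.hexamer] = {n - h - 6 for h in minus_rc}
        for site in sites:
            table = editable_plus if site.strand == "+" else editable_minus
            flagged = site.interval[0] in table[site.hexamer]
            records.append(EditablePASRecord(site, (), flagged))
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'direct' or 'regex'")
    return records


def scan(
    seqs: Mapping[str, str] | Iterable[tuple[str, str]],
    editor: EditorSpec,
    motifs: Sequence[PASMotifSpec],
    engine: str = "direct",
    include_softmasked: bool = True,
) -> list[EditablePASRecord]:
    """Scan a sequence collection for editable PAS sites.

    ``seqs`` maps sequence name -> sequence (or yields such pairs); each
    sequence is scanned independently.  Soft-masked (lowercase) bases are
    uppercased before matching unless ``include_softmasked`` is False, in
    which case they are replaced by N and therefore excluded.
    """
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records: list[EditablePASRecord] = []
    for chrom, seq in items:
        seq = str(seq)
        if not include_softmasked:
            seq = "".join("N" if b.islower() else b for b in seq)
        found = _scan_sequence(chrom, seq, editor, motifs, engine)
        records.extend(found)
        logger.info("scanned %s (%d bp): %d motif sites", chrom, len(seq), len(found))
    return records


def scan_fasta(
    path: str | Path,
    editor: EditorSpec,
    motifs: Sequence[PASMotifSpec],
    engine: str = "direct",
    include_softmasked: bool = True,
) -> list[EditablePASRecord]:
    """Scan a FASTA file (plain or bgzip); names are taken from the
    headers up to the first whitespace."""
    try:
        fasta = Fasta(str(path), rebuild=False)
    except Exception as exc:  # pyfaidx raises several types
        raise IOError(f"cannot read FASTA {path}: {exc}") from exc
    pairs = ((name, str(fasta[name][:])) for name in fasta.keys())
    return scan(pairs, editor, motifs, engine=engine, include_softmasked=include_softmasked)


# --- output -----------------------------------------------------------------

def _sorted_records(records: Sequence[EditablePASRecord]) -> list[EditablePASRecord]:
    return sorted(records, key=lambda r: (r.site.chrom, r.site.interval[0], r.site.strand))


def write_bed(records: Sequence[EditablePASRecord], path: str | Path) -> None:
    """BED6 per site: name = motif hexamer, score = guide count (for the
    regex engine, which carries no guide list, 1/0 editability)."""
    rows = []
    for r in _sorted_records(records):
        score = len(r.guides) if r.guides else int(r.editable)
        rows.append(
            (r.site.chrom, r.site.interval[0], r.site.interval[1], r.site.hexamer, score, r.site.strand)
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    df.to_csv(path, sep="\t", header=False, index=False)


def write_guides_tsv(records: Sequence[EditablePASRecord], path: str | Path) -> None:
    """One row per guide candidate; empty (header-only) when no guides."""
    rows = []
    for r in _sorted_records(records):
        for g in r.guides:
            rows.append(
                {
                    "chrom": r.site.chrom,
                    "site_start": r.site.interval[0],
                    "site_end": r.site.interval[1],
                    "site_strand": r.site.strand,
                    "motif": r.site.hexamer,
                    "guide_strand": g.placement.guide_strand,
                    "strand_mode": g.strand_mode,
                    "protospacer": g.protospacer_seq,
                    "pam": g.pam_seq,
                    "protospacer_start": g.placement.protospacer_interval[0],
                    "protospacer_end": g.placement.protospacer_interval[1],
                    "window_positions": ",".join(str(w) for _, w in g.captured_positions),
                    "captured_positions": ",".join(str(p) for p, _ in g.captured_positions),
                    "predicted_hexamers": ",".join(sorted(g.predicted_hexamers)),
                }
            )
    df = pd.DataFrame(rows, columns=GUIDE_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_scan_bed(path: str | Path) -> list[EditablePASRecord]:
    """Re-read a scan BED6 into minimal records (editable iff score > 0)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return []
    records = []
    for row in df.itertuples(index=False):
        site = MotifSite(row.chrom, (int(row.start), int(row.end)), row.strand, row.name)
        records.append(EditablePASRecord(site, (), int(row.score) > 0))
    return records
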