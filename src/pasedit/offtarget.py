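"""Brute-force off-target enumeration and the three-criterion filter.

Every protospacer-length placement on both strands of the genome is
tested: a locus is a candidate off-target site when its adjacent PAM
matches the editor's IUPAC pattern and it carries at most ``max_mismatches``
mismatches to the query protospacer.  PAM mismatches are never counted in
the total — a locus whose PAM does not match is simply not a site.

Candidate sites are then annotated with three verdicts:

1. *mismatch geometry* — all mismatches lie outside the PAM and outside
   the PAM-proximal seed region, and there are at most ``max_mm_outside``
   of them (strict reading; a looser reading that merely ignores seed
   mismatches when counting is available via ``strict=False``);
2. *editable window* — the site contains at least one source base
   (adenine, for A->G editors) inside the activity window;
3. *single-copy locus* — the full protospacer+PAM sequence occurs exactly
   once genome-wide (both strands).

The seed length is configurable and defaults to the PAM-proximal 12
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._seq import DNA, is_unambiguous, matches_iupac, revcomp
from .editor_model import EditorSpec


@dataclass(frozen=True)
class OffTargetQuery:
    """A protospacer+PAM query with enumeration limits."""

    protospacer: str
    pam: str = "NGG"
    max_mismatches: int = 4
    seed_len: int = 12

    def __post_init__(self) -> None:
        p = self.protospacer.upper()
        object.__setattr__(self, "protospacer", p)
        if not p or not is_unambiguous(p):
            raise ValueError("protospacer must be a non-empty ACGT string")
        if not 0 <= self.max_mismatches <= len(p):
            raise ValueError("max_mismatches outside [0, protospacer length]")
        if not 0 <= self.seed_len <= len(p):
            raise ValueError("seed_len outside [0, protospacer length]")


@dataclass(frozen=True)
class OffTargetSite:
    """One near-match locus with per-position mismatch annotation.

    ``interval`` spans the protospacer on the plus strand;
    ``mismatch_positions`` are 1-based from the protospacer 5' end;
    ``copy_count`` counts genome-wide occurrences of the protospacer+PAM
    sequence on both strands.  Verdict fields are ``None`` until
    :func:`apply_filters` runs.
    """

    chrom: str
    interval: tuple[int, int]
    strand: str
    site_seq: str
    pam_seq: str
    mismatch_positions: tuple[int, ...]
    window_source_count: int
    copy_count: int
    criterion_mismatches: bool | None = None
    criterion_window: bool | None = None
    criterion_single_copy: bool | None = None

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)

    @property
    def is_on_target(self) -> bool:
        return self.mismatch_count == 0

    @property
    def passes_all(self) -> bool:
        return bool(self.criterion_mismatches and self.criterion_window and self.criterion_single_copy)


def _count_occurrences(haystacks: Sequence[str], needle: str) -> int:
    """Overlap-tolerant exact occurrence count over both strands."""
    total = 0
    for target in (needle, revcomp(needle)):
        for hs in haystacks:
            start = hs.find(target)
            while start != -1:
                total += 1
                start = hs.find(target, start + 1)
    return total


def enumerate_near_matches(
    genome: Mapping[str, str],
    query: OffTargetQuery,
    editor: EditorSpec | None = None,
) -> list[OffTargetSite]:
    """Every PAM-adjacent locus within ``query.max_mismatches`` of the
    protospacer, on both strands of every contig.

    The perfect-match on-target site is included with zero mismatches
    (see :attr:`OffTargetSite.is_on_target`).  ``editor`` supplies the
    activity window for the window source-base annotation (defaults to
    the ABEmax geometry) and must agree with the query's protospacer
    length.
    """
    if editor is None:
        editor = EditorSpec("spcas9-abemax", pam=query.pam)
    L = len(query.protospacer)
    if L != editor.protospacer_len:
        raise ValueError(
            f"query protospacer length {L} != editor protospacer_len {editor.protospacer_len}"
        )
    npam = len(query.pam)
    lo, hi = editor.window
    src = editor.source_base
    seqs = {chrom: str(seq).upper() for chrom, seq in genome.items()}
    sites: list[OffTargetSite] = []
    for chrom, seq in seqs.items():
        n = len(seq)
        for rc_strand, s in (("+", seq), ("-", revcomp(seq))):
            for start in range(0, n - L - npam + 1):
                pam_seq = s[start + L : start + L + npam]
                if not matches_iupac(pam_seq, query.pam):
                    continue
                proto = s[start : start + L]
                if not is_unambiguous(proto):
                    continue
                mism = [
                    i + 1 for i in range(L) if proto[i] != query.protospacer[i]
                ]
                if len(mism) > query.max_mismatches:
                    continue
                if rc_strand == "+":
                    interval = (start, start + L)
                else:
                    interval = (n - start - L, n - start)
                sites.append(
                    OffTargetSite(
                        chrom=chrom,
                        interval=interval,
                        strand=rc_strand,
                        site_seq=proto,
                        pam_seq=pam_seq,
                        mismatch_positions=tuple(mism),
                        window_source_count=sum(
                            1 for w in range(lo, hi + 1) if proto[w - 1] == src
                        ),
                        copy_count=_count_occurrences(
                            list(seqs.values()), proto + pam_seq
                        ),
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.interval, s.strand))
    return sites


def apply_filters(
    sites: Sequence[OffTargetSite],
    editor: EditorSpec | None = None,
    seed_len: int = 12,
    max_mm_outside: int = 4,
    strict: bool = True,
) -> list[OffTargetSite]:
    """Annotate each site with the three criterion verdicts.

    With protospacer length L the seed region is the PAM-proximal
    ``seed_len`` positions, i.e. 1-based positions L-seed_len+1 .. L.
    Returns all sites with verdicts filled in; the filtered candidate
    list is ``[s for s in result if s.passes_all]``.
    """
    out = []
    for site in sites:
        L = len(site.site_seq)
        seed_start = L - seed_len + 1  # first 1-based seed position
        outside = [p for p in site.mismatch_positions if p < seed_start]
        if strict:
            c1 = len(outside) == len(site.mismatch_positions) and len(outside) <= max_mm_outside
        else:
            c1 = len(outside) <= max_mm_outside
        out.append(
            replace(
                site,
                criterion_mismatches=c1,
                criterion_window=site.window_source_count >= 1,
                criterion_single_copy=site.copy_count == 1,
            )
        )
    return out


def passing_sites(sites: Sequence[OffTargetSite]) -> list[OffTargetSite]:
    return [s for s in sites if s.passes_all]


def write_offtarget_tsv(sites: Sequence[OffTargetSite], path: str | Path) -> None:
    cols = [
        "chrom", "start", "end", "strand", "site_seq", "pam_seq",
        "mismatch_count", "mismatch_positions", "window_source_count",
        "copy_count", "criterion_mismatches", "criterion_window",
        "criterion_single_copy", "passes_all",
    ]
    rows = [
        {
            "chrom": s.chrom,
            "start": s.interval[0],
            "end": s.interval[1],
            "strand": s.strand,
            "site_seq": s.site_seq,
            "pam_seq": s.pam_seq,
            "mismatch_count": s.mismatch_count,
            "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
            "window_source_count": s.window_source_count,
            "copy_count": s.copy_count,
            "criterion_mismatches": s.criterion_mismatches,
            "criterion_window": s.criterion_window,
            "criterion_single_copy": s.criterion_single_copy,
            "passes_all": s.passes_all,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
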