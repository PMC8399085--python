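"""PAS annotation intake, hexamer classification, and editability summaries.

Reads polyadenylation-signal annotations in the GENCODE polyA GFF3
dialect (feature type ``polyA_signal``, 1-based closed coordinates) or
BED6, classifies each annotated hexamer against the reference, and joins
annotations with scan output to compute the two headline statistics:

* the share of annotated PASs carrying one of the two canonical hexamers
  (AATAAA/ATTAAA), and
* the fraction of those two-motif PASs that a base editor can disrupt.

Joining is exact on (chrom, interval, strand): GENCODE ``polyA_signal``
features are precise hexamer spans, so an annotation is editable iff a
scan record at the identical span is editable, never by proximity.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from ._seq import is_unambiguous, revcomp
from .genome_scan import EditablePASRecord

logger = logging.getLogger(__name__)

TWO_MOTIFS = ("AATAAA", "ATTAAA")
CLASSES = ("AATAAA", "ATTAAA", "other", "unextractable")


@dataclass(frozen=True)
class PASAnnotation:
    """One annotated PAS: 0-based half-open interval on the plus strand."""

    chrom: str
    interval: tuple[int, int]
    strand: str
    feature_type: str = "polyA_signal"
    hexamer: str | None = None
    motif_class: str | None = None

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.interval[0], self.interval[1], self.strand)


@dataclass(frozen=True)
class EditabilitySummary:
    """Motif-class counts plus the editable fraction of two-motif PASs."""

    class_counts: Mapping[str, int]
    total: int
    two_motif_total: int
    editable_count: int
    coding_editable: int
    template_editable: int

    @property
    def two_motif_share(self) -> float | None:
        return self.two_motif_total / self.total if self.total else None

    @property
    def editable_fraction(self) -> float | None:
        return self.editable_count / self.two_motif_total if self.two_motif_total else None


def read_polya_gff3(path: str | Path) -> list[PASAnnotation]:
    """Parse ``polyA_signal`` features from a GENCODE-style polyA GFF3.

    Other feature types (``polyA_site``, ``pseudo_polyA``) are dropped;
    malformed lines are skipped and counted; identical
    (chrom, interval, strand) tuples — e.g. the same signal annotated on
    several transcript isoforms — are deduplicated.  1-based closed GFF3
    coordinates become 0-based half-open.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"polyA GFF3 not found: {path}")
    annots: list[PASAnnotation] = []
    seen: set[tuple] = set()
    malformed = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception:
                malformed += 1
                continue
            if feat.featuretype != "polyA_signal":
                continue
            strand = feat.strand if feat.strand in "+-" else "+"
            ann = PASAnnotation(feat.seqid, (feat.start - 1, feat.end), strand)
            if ann.key in seen:
                continue
            seen.add(ann.key)
            annots.append(ann)
    if malformed:
        logger.warning("skipped %d malformed GFF3 lines in %s", malformed, path)
    if not annots:
        warnings.warn(f"no polyA_signal features found in {path}", stacklevel=2)
    return annots


def read_polya_bed(path: str | Path) -> list[PASAnnotation]:
    """Read PAS annotations from a 6-column BED (already 0-based)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return []
    out, seen = [], set()
    for row in df.itertuples(index=False):
        ann = PASAnnotation(row.chrom, (int(row.start), int(row.end)), row.strand)
        if ann.key not in seen:
            seen.add(ann.key)
            out.append(ann)
    return out


def classify_annotations(
    annotations: Sequence[PASAnnotation], genome: Mapping[str, str]
) -> list[PASAnnotation]:
    """Extract each annotation's hexamer from the reference and class it.

    Classes: the two canonical hexamers, ``other`` (any other extractable
    ACGT hexamer), or ``unextractable`` (span not 6 nt, contig missing,
    off-contig coordinates, or ambiguity codes in the span).
    """
    missing_contigs: set[str] = set()
    out = []
    for ann in annotations:
        start, end = ann.interval
        seq = genome.get(ann.chrom)
        if seq is None:
            missing_contigs.add(ann.chrom)
            out.append(replace(ann, hexamer=None, motif_class="unextractable"))
            continue
        if end - start != 6 or start < 0 or end > len(seq):
            out.append(replace(ann, hexamer=None, motif_class="unextractable"))
            continue
        hexamer = str(seq[start:end]).upper()
        if ann.strand == "-":
            hexamer = revcomp(hexamer)
        if not is_unambiguous(hexamer):
            out.append(replace(ann, hexamer=None, motif_class="unextractable"))
            continue
        cls = hexamer if hexamer in TWO_MOTIFS else "other"
        out.append(replace(ann, hexamer=hexamer, motif_class=cls))
    if missing_contigs:
        warnings.warn(
            f"contigs absent from genome: {sorted(missing_contigs)}", stacklevel=2
        )
    return out


def classify_and_summarize(
    annotations: Sequence[PASAnnotation], genome: Mapping[str, str]
) -> tuple[list[PASAnnotation], dict[str, int]]:
    """Classify hexamers and return per-class counts (all classes keyed)."""
    classified = classify_annotations(annotations, genome)
    counts = Counter(a.motif_class for a in classified)
    return classified, {cls: counts.get(cls, 0) for cls in CLASSES}


def editability_summary(
    annotations: Sequence[PASAnnotation],
    scan_records: Sequence[EditablePASRecord],
) -> EditabilitySummary:
    """Join classified annotations with scan records on the exact hexamer
    span and summarise editability over the two-motif denominator.

    Annotations classed ``other``/``unextractable`` are excluded from the
    denominator.  An annotation without a matching scan record counts as
    non-editable.  The per-mode breakdown requires direct-engine records
    (guide lists); with regex-engine records it reports zero.
    """
    if any(a.motif_class is None for a in annotations):
        raise ValueError("annotations must be classified first (classify_annotations)")
    by_key = {r.site.key: r for r in scan_records}
    counts = Counter(a.motif_class for a in annotations)
    two_motif = [a for a in annotations if a.motif_class in TWO_MOTIFS]
    editable = coding = template = 0
    joined = 0
    for ann in two_motif:
        rec = by_key.get(ann.key)
        if rec is None:
            continue
        joined += 1
        if rec.editable:
            editable += 1
            modes = {g.strand_mode for g in rec.guides}
            coding += "coding" in modes
            template += "template" in modes
    if two_motif and joined == 0 and _any_near_join(two_motif, scan_records):
        warnings.warn(
            "no exact (chrom, interval, strand) joins but near-matches exist: "
            "possible coordinate-system mismatch (0-based vs 1-based?)",
            stacklevel=2,
        )
    return EditabilitySummary(
        class_counts={cls: counts.get(cls, 0) for cls in CLASSES},
        total=len(annotations),
        two_motif_total=len(two_motif),
        editable_count=editable,
        coding_editable=coding,
        template_editable=template,
    )


def _any_near_join(
    annotations: Sequence[PASAnnotation], records: Sequence[EditablePASRecord]
) -> bool:
    starts = {(r.site.chrom, r.site.strand): set() for r in records}
    for r in records:
        starts[(r.site.chrom, r.site.strand)].add(r.site.interval[0])
    for ann in annotations:
        pool = starts.get((ann.chrom, ann.strand), ())
        if any(ann.interval[0] + d in pool for d in (-2, -1, 1, 2)):
            return True
    return False


def write_summary_tsv(summary: EditabilitySummary, path: str | Path) -> None:
    rows = [("n_annotations", summary.total)]
    rows += [(f"n_{cls}", n) for cls, n in summary.class_counts.items()]
    rows += [
        ("n_two_motif", summary.two_motif_total),
        ("two_motif_share", "NA" if summary.two_motif_share is None else f"{summary.two_motif_share:.4f}"),
        ("n_editable_two_motif", summary.editable_count),
        ("editable_fraction", "NA" if summary.editable_fraction is None else f"{summary.editable_fraction:.4f}"),
        ("n_editable_coding", summary.coding_editable),
        ("n_editable_template", summary.template_editable),
    ]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, sep="\t", index=False)
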