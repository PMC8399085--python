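"""Intersect annotated polyadenylation signals with a scan.

Builds a toy genome carrying five annotated PASs (three AATAAA, one
ATTAAA, one non-canonical AGTAAA) of which exactly one has a reachable
PAM, writes a GENCODE-style polyA GFF3, and reproduces the two headline
statistics: the canonical-motif share and the editable fraction.
"""

import tempfile
from pathlib import Path

from pasedit import (
    classify_annotations,
    default_motifs,
    editability_summary,
    get_editor,
    read_polya_gff3,
    scan,
)

editor = get_editor("spcas9-abemax")
motifs = default_motifs()

spacer = "ATATAT" * 6
contexts = [
    ("AATAAA", "ATCATCATCATCAT" + "TGG"),   # PAM at a 14-nt gap: editable
    ("AATAAA", "ATCATCATCATCATCATCA"),       # no PAM in range
    ("AATAAA", "ATCATCATCATCATCATCA"),
    ("ATTAAA", "ATCATCATCATCATCATCA"),
    ("AGTAAA", "ATCATCATCATCATCATCA"),       # non-canonical hexamer
]
pieces, starts, offset = ["ACAC" * 10], [], 40
for hexamer, ctx in contexts:
    starts.append(offset)
    pieces.append(hexamer + ctx + spacer)
    offset += len(pieces[-1])
genome = {"toy1": "".join(pieces)}

with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "toy.polyA.gff3"
    lines = ["##gff-version 3"] + [
        f"toy1\ttoy\tpolyA_signal\t{s + 1}\t{s + 6}\t.\t+\t.\tID=pas{i}"
        for i, s in enumerate(starts)
    ]
    gff.write_text("\n".join(lines) + "\n")
    annots = classify_annotations(read_polya_gff3(gff), genome)

summary = editability_summary(annots, scan(genome, editor, motifs))
print("motif-class counts:", dict(summary.class_counts))
print(f"two-motif share: {100 * summary.two_motif_share:.0f}%"
      f"  ({summary.two_motif_total}/{summary.total})")
print(f"editable fraction: {100 * summary.editable_fraction:.0f}%"
      f"  ({summary.editable_count}/{summary.two_motif_total})")
# 4 of 5 annotated signals carry a canonical hexamer (80%), and 1 of
# those 4 is disruptable by the base editor (25%).
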