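# pasedit

Genome-wide discovery of polyadenylation signals (PAS) that a CRISPR
adenine base editor can disrupt, and screening of the off-target
candidates such a guide would create.

## The problem

Cleavage and polyadenylation of a pre-mRNA is directed by a hexameric
PAS, canonically `AATAAA` or `ATTAAA`. Destroying the hexamer destabilises
the transcript, which makes the PAS an attractive target for silencing a
gene without cutting its coding sequence — the motivating case being the
somatic PAS of *DUX4*, whose presence on the 4qA subtelomere is a genetic
prerequisite for facioscapulohumeral muscular dystrophy (FSHD). An
adenine base editor (ABE: a Cas9 nickase fused to an adenosine deaminase)
converts A·T to G·C without double-strand breaks, but only for adenines
that fall inside its **activity window** — protospacer positions ~4–8
counted from the 5′ (PAM-distal) end — and only where an **NGG PAM** sits
immediately 3′ of the protospacer.

A canonical PAS can be disrupted two ways:

* **coding strand** — edit any adenine of the last three hexamer
  positions (`AATAAA → AATAAG`, …), guide on the hexamer strand;
* **template strand** — edit the adenine that pairs with the middle
  thymine (hexamer position 3), guide on the opposite strand, which
  reads `ATTAAA → ATCAAA` on the coding strand: precisely the natural
  chromosome-10 variant that renders the *DUX4* PAS non-functional.

Whether a disruptable base is reachable is pure geometry. For protospacer
length *L*, disruptable hexamer position *p* and window position *w*, the
hexamer-to-PAM gap is *g = p − w + L − 6* (coding) or *g = L + 1 − p − w*
(template); over the default ABEmax geometry this gives gaps of 10–16 nt
(coding) and 10–14 nt (template). A PAS is **editable** iff a PAM-matched,
in-bounds, ambiguity-free placement exists for at least one disruptable
base on either strand.

`pasedit` implements this eligibility model as a library with a thin CLI:

* `editor_model` — editor/motif specifications and placement geometry;
* `genome_scan` — two interchangeable genome-wide engines (a
  regular-expression construction and a direct positional enumeration)
  with BED6/TSV output;
* `annotation` — GENCODE polyA GFF3/BED intake, hexamer classification,
  and the editable-fraction summary over annotated signals;
* `offtarget` — brute-force near-match enumeration plus the
  three-criterion candidate filter (mismatches outside PAM+seed and ≤ 4;
  ≥ 1 window adenine; single-copy locus);
* `synthetic_fixtures` — deterministic test genomes with planted truth
  and the exhaustive oracles used as ground truth.

It models *eligibility* only — editing efficiency, chromatin context and
transcript-level consequences are out of scope.

## Worked example

```python
from pasedit import (MotifSite, PASMotifSpec, enumerate_guides_for_site,
                     get_editor)

editor = get_editor("spcas9-abemax")           # NGG, 20 nt, window 4-8, A->G
seq = "ATTAAA" + "ATCATCATCATCAT" + "TGG"      # hexamer, 14-nt gap, PAM
site = MotifSite("dux4_exon3", (0, 6), "+", "ATTAAA")
guides = enumerate_guides_for_site(site, editor, PASMotifSpec("ATTAAA"), seq)
```

Running `python examples/01_dux4_guide_geometry.py` prints:

```
sequence: ATTAAAATCATCATCATCATTGG
guides found: 1
  protospacer ATTAAAATCATCATCATCAT  PAM TGG  mode coding
  hexamer position 4 sits at window position 4
  hexamer position 5 sits at window position 5
  hexamer position 6 sits at window position 6
  predicted mutant hexamers: ['ATTAAG', 'ATTAGA', 'ATTGAA']

template-strand edit of ATTAAA position 3 -> ATCAAA
```

One guide places the hexamer's last three adenines at window positions
4–6; any single conversion yields a hexamer that is no longer a canonical
PAS. The other examples (`examples/02`–`04`) scan a synthetic genome with
both engines, reproduce the annotation summary statistics (80 %
canonical-motif share, 25 % editable fraction on the constructed toy),
and run the off-target filter.

The same operations are available from a shell:

```bash
pasedit simulate --seed 11 --length 25000 --out-prefix fx
pasedit scan --fasta fx.fa --editor spcas9-abemax --out-bed scan.bed --out-guides guides.tsv
pasedit summarize --fasta fx.fa --polya polyA.gff3 --scan-bed scan.bed --out summary.tsv
pasedit offtarget --fasta fx.fa --protospacer ATTAAAATCATCATCATCAT --out ot.tsv
```

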