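# Methods

## Eligibility model

A base editor is described by four targeting parameters: an IUPAC PAM
pattern read immediately 3′ of the protospacer on the protospacer strand
(`NGG`), the protospacer length (20 nt), an inclusive activity window in
1-based protospacer coordinates counted from the 5′/PAM-distal end
(default 4–8), and a source→product conversion (A→G). The shipped
presets `spcas9-abemax` and `spcas9-abe7.10` share this geometry; the
window bounds are configurable because published window estimates differ
between ABE versions, and 4–8 is adopted as the default for both — the
positions at which A4–A6 editing is observed with ABEmax and which are
still described as in-window for ABE7.10.

A PAS motif is a hexamer plus its disruptable positions. For `AATAAA`
and `ATTAAA` the defaults are coding-strand positions {4, 5, 6} (the last
three adenines) and template-strand position {3} (the adenine pairing
with the middle thymine). Two deliberate restrictions are kept exactly:
position 2 of `ATTAAA` (also a T) is not a default template target, and
positions 1–2 of `AATAAA` (also adenines) are not default coding targets.
Both sets are configurable per motif. A1/A2 edits of `AATAAA` would
produce single-substitution variants that are themselves known weak PAS
hexamers, which is a plausible reason to exclude them, so the
conservative rule is the default.

Editing chemistry acts on the protospacer-strand base, so the guide
always lies on the strand carrying the source adenine: coding-mode guides
on the hexamer strand, template-mode guides opposite. For protospacer
length *L*, disruptable position *p* and window position *w*, the
hexamer-to-PAM gap is

* coding: `g = p − w + (L − 6)` — measured hexamer 3′ end → PAM start;
* template: `g = L + 1 − p − w` — measured PAM end → hexamer 5′ start in
  the plus-strand view of the reverse-strand guide.

With the defaults these ranges are [10, 16] and [10, 14]; they are always
derived by enumeration over (p, w), never stored.

Predicted mutant hexamers substitute source→product at the edited coding
position, or the complement of the product base at a template position
(T→C on the coding strand). For the default motifs every reachable edit
leaves the canonical motif set; this is asserted as a test property, not
assumed.

## Scan engines

Both engines first locate every hexamer occurrence on both strands
(overlaps included; minus-strand occurrences carry plus-strand intervals)
and then decide editability per occurrence.

The **direct** engine enumerates placements for every disruptable
position and groups placements sharing (guide strand, protospacer
interval) into one guide candidate listing all captured positions — a
window that spans several disruptable adenines yields one candidate, not
duplicates.

The **regex** engine compiles, per motif and strand mode, a plus-strand
pattern `HEXAMER [ACGT]{lo,hi} PAM` (coding) or
`revcomp(PAM) [ACGT]{lo,hi} HEXAMER` (template), with `lo,hi` taken from
the gap range; minus-strand occurrences are found by scanning the reverse
complement and mirroring coordinates. Two corrections are required to
make pattern matching exact rather than approximately right:

1. *Overlap tolerance.* The search restarts one base after each match
   start, so nearby occurrences sharing context are not masked by the
   gap quantifier. For the template-shaped pattern the hexamer sits at
   the match **end**, and a single PAM anchor can reach several hexamers
   of which a greedy (or lazy) quantifier reports exactly one; every
   in-range hexamer offset from each match start is therefore
   enumerated explicitly.
2. *Edge confirmation.* A match proves hexamer + gap + PAM, but the
   implied protospacer extends up to `L − 6 − lo` bases beyond the
   matched span and may leave the sequence or cross an ambiguity code.
   Each anchored hexamer is confirmed by checking the gap values in
   range for an in-bounds, N-free protospacer + PAM.

With both corrections the two engines agree exactly — the test suite
demands identical editable-site sets against an independent exhaustive
oracle on 100 random 10-kb genomes, including AT-rich genomes with
overlapping occurrences and sequences shorter than a protospacer.

Ambiguity codes: a genome `N` never matches the source base and never
satisfies any PAM symbol, so no emitted protospacer or PAM contains `N`.
Soft-masked lowercase is uppercased by default; an option converts it to
`N` to exclude masked regions.

## Annotation intersection

GFF3 intake keeps only `polyA_signal` features (the GENCODE polyA
dialect), converts 1-based closed to 0-based half-open coordinates,
skips and counts malformed lines, and deduplicates identical
(chrom, interval, strand) tuples — the same signal is annotated once per
transcript isoform in GENCODE, and the statistic of interest is per
site, not per transcript. Hexamers are extracted from the reference on
the annotated strand and classed `AATAAA`/`ATTAAA`/`other`/
`unextractable` (wrong span length, missing contig, out of bounds, or
ambiguity codes).

The editability join is exact on (chrom, interval, strand): polyA_signal
features are precise hexamer spans, so proximity matching would only
manufacture false joins. An annotation without a matching scan record
counts as non-editable; the editable-fraction denominator is the
two-canonical-motif class only. A heuristic warns when zero exact joins
coexist with near-joins shifted by 1–2 bp, the signature of a
coordinate-convention mismatch.

Genome-scale values of the two headline statistics (canonical-motif
share ≈ 80 %, editable share ≈ 25 % on human annotation data) require the
external reference genome and annotation and are not shipped; the same
code path is exercised on constructed five-signal and four-signal toys
whose shares are 80 % and 25 % by construction.

## Off-target model

Enumeration is a brute-force contract: every protospacer-length placement
on both strands is tested for a PAM match and Hamming distance to the
query (≤ 4 mismatches by default); PAM-mismatched loci are not sites and
PAM positions never count toward mismatch totals. The perfect match is
included and flagged as on-target.

The three filter criteria are annotated separately and recomputable from
the stored fields:

1. all mismatches outside the PAM and outside the PAM-proximal **seed**,
   and at most 4 of them. The seed length is nowhere standardised; 12
   PAM-proximal positions is the default and it is configurable. A
   looser reading — count only non-seed mismatches against the limit,
   tolerating seed mismatches — is available behind a flag
   (`strict=False` / `--loose-seed-count`);
2. at least one source base (adenine) inside the activity window of the
   site sequence;
3. single-copy locus, operationalised as: the exact
   protospacer+PAM-length sequence occurs exactly once genome-wide over
   both strands. Alignment-based uniqueness of external search tools is
   deliberately not reproduced.

## Synthetic fixtures and oracles

The generator plants features in evenly blocked, randomly jittered,
non-overlapping slots (≥ 150 bp of genome per plant) on random strands:
editable sites with an intended PAM at a drawn in-range gap; decoys whose
17–22 nt guard flanks exclude `GG`/`CC` dinucleotides so no in-range PAM
can exist (including across the guard/background junction, which the
guard lengths place out of range by construction); a wrong-gap decoy with
its only `GG` at gap 18; `ATCAAA` pseudo-motif and non-canonical hexamer
plants; and off-target variants with chosen mismatch positions. The
background is uniform ACGT (an AT-rich mode exists to stress overlap
handling) and is *scrubbed*: accidental canonical-motif words and
accidental near-matches to the off-target query are resampled in place
until none survive outside the plants. Whole-genome rejection sampling
would not terminate at this scale — a random 10-kb sequence already
contains ~10 motif occurrences, about half with an in-range PAM — so
targeted resampling is the practical form of rejection.

Before a fixture is emitted it must pass a self-consistency gate: the
exhaustive oracles re-scan the finished sequence, and the motif-site set,
the editable subset and the near-match set must equal the manifest
exactly; otherwise the build retries from a derived seed. Editability
truths are by construction; per-site guide *counts* are taken from the
oracle at generation time (extra PAMs in the unguarded background of an
editable plant legitimately add guides). All randomness flows through a
single seeded generator, so identical specs give byte-identical output.

The oracles are intentionally unoptimised and share no matching code with
the engines: they keep local complement and IUPAC tables, enumerate every
(hexamer position × disruptable position × window position × strand)
combination from first principles, and slide a Hamming window for
near-matches with the minus strand handled by complementing the query in
place rather than reverse-complementing the sequence.

What the fixtures do *not* emulate: real base composition and repeat
structure, soft-masking, assembly gaps, chromatin accessibility, and any
notion of editing efficiency. Passing fixture-recovery tests therefore
demonstrates correctness of the geometry, scanning and filtering logic —
not biological performance on a real genome.

## Problem sizes and numerical choices

Test-suite equivalence runs use 100 random 10-kb genomes (scan) and 50
(off-target); the acceptance script uses 30 and 15 fresh genomes drawn
from its seed — sizes at which the exhaustive oracles finish in seconds
while still covering thousands of motif occurrences. Property suites run
200 randomized cases each, derandomised for reproducibility. Outputs are
deterministically sorted by (chrom, start, strand); records never extend
past sequence bounds; degenerate inputs (empty FASTA, empty annotation
lists, zero-feature GFF3) return empty results with warnings rather than
errors.

## Known limitations

* Eligibility only: no model of per-position editing efficiency, bystander
  edits outside the hexamer, or transcript-level outcome.
* The activity-window default and the 12-nt seed default are documented
  assumptions, not measured constants; both are parameters.
* Copy-number uniqueness is exact-string, not alignment-based.
* The regex engine reports editability flags only (its guide list is
  empty by design); use the direct engine when guide sequences are
  needed downstream.
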