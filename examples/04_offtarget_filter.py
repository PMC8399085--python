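"""Enumerate and filter off-target candidates for a guide.

Plants several near-match loci for a random query guide in a synthetic
genome — including an exact duplicate (multi-copy locus) and a variant
with a seed-region mismatch — then applies the three candidate criteria:
(1) all mismatches outside PAM and seed, at most 4; (2) at least one
adenine in the editing window; (3) single-copy locus.
"""

from pasedit import (
    FixtureSpec,
    OffTargetQuery,
    apply_filters,
    enumerate_near_matches,
    generate,
    get_editor,
)

editor = get_editor("spcas9-abemax")
spec = FixtureSpec(
    seed=3, length=30_000, n_coding_editable=1,
    offtarget_plants=((), (), (1, 3), (2,), (1, 20), (5, 6, 7, 8)),
)
genome, manifest = generate(spec)
query = OffTargetQuery(manifest.protospacer)

sites = apply_filters(enumerate_near_matches(genome, query, editor), editor)
print(f"query protospacer: {query.protospacer}")
print(f"{len(sites)} near-match loci (<= {query.max_mismatches} mismatches, NGG PAM)")
for s in sites:
    tag = "on-target" if s.is_on_target else f"mm at {s.mismatch_positions}"
    print(f"  {s.chrom}:{s.interval[0]} {s.strand}  {tag:<22}"
          f" copies={s.copy_count}"
          f"  c1={s.criterion_mismatches} c2={s.criterion_window}"
          f" c3={s.criterion_single_copy}  -> {'PASS' if s.passes_all else 'drop'}")
# The duplicated exact locus fails the single-copy criterion and the
# variant with a mismatch at protospacer position 20 (inside the
# PAM-proximal 12-nt seed) fails criterion 1; the remaining variants
# keep a window adenine and pass all three.
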