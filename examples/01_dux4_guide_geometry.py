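"""Design a disrupting guide for a DUX4-style polyadenylation signal.

The DUX4 somatic PAS (ATTAAA) has a TGG PAM 14 nt downstream of the
hexamer, which places its last three adenines in the ABEmax activity
window.  The same context with ATCAAA — the naturally non-functional
chromosome-10 variant — is not a PAS motif at all, and the template-strand
edit of ATTAAA converts it into exactly that variant.
"""

from pasedit import (
    MotifSite,
    PASMotifSpec,
    enumerate_guides_for_site,
    get_editor,
    predicted_edited_hexamer,
)

editor = get_editor("spcas9-abemax")
seq = "ATTAAA" + "ATCATCATCATCAT" + "TGG"

site = MotifSite("dux4_exon3", (0, 6), "+", "ATTAAA")
guides = enumerate_guides_for_site(site, editor, PASMotifSpec("ATTAAA"), seq)

print(f"sequence: {seq}")
print(f"guides found: {len(guides)}")
for g in guides:
    print(f"  protospacer {g.protospacer_seq}  PAM {g.pam_seq}  mode {g.strand_mode}")
    for hex_pos, window_pos in g.captured_positions:
        print(f"  hexamer position {hex_pos} sits at window position {window_pos}")
    print(f"  predicted mutant hexamers: {sorted(g.predicted_hexamers)}")

print()
print("template-strand edit of ATTAAA position 3 ->",
      predicted_edited_hexamer(PASMotifSpec("ATTAAA"), 3, "template"))
# One guide captures hexamer adenines 4-6 at window positions 4-6; each
# single A->G (or T->C on the coding strand) edit destroys the PAS motif.
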