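"""Small shared sequence helpers (IUPAC matching, reverse complement)."""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _bio_revcomp

DNA = frozenset("ACGT")

#: IUPAC symbol -> set of concrete bases it stands for (e.g. N -> {A,C,G,T}).
IUPAC_BASES: dict[str, frozenset[str]] = {
    sym: frozenset(bases) for sym, bases in ambiguous_dna_values.items()
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via biopython)."""
    return _bio_revcomp(seq)


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff every base of ``seq`` is a concrete ACGT base allowed by the
    corresponding IUPAC symbol of ``pattern``.

    A genome ``N`` (or any other ambiguity code in the genome) never
    satisfies any pattern symbol, including pattern ``N``: ambiguous
    reference bases are treated as unscannable, so no placement containing
    them is ever reported.
    """
    if len(seq) != len(pattern):
        return False
    for base, sym in zip(seq, pattern):
        if base not in DNA:
            return False
        if base not in IUPAC_BASES.get(sym, ()):
            return False
    return True


def iupac_char_class(sym: str) -> str:
    """Regex character class for one IUPAC symbol, e.g. R -> ``[AG]``."""
    bases = sorted(IUPAC_BASES[sym])
    if len(bases) == 1:
        return bases[0]
    return "[" + "".join(bases) + "]"


def is_unambiguous(seq: str) -> bool:
    return all(b in DNA for b in seq)
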