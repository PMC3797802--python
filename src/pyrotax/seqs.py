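"""Small nucleotide helpers: IUPAC classes, complements, mismatch counting."""

from __future__ import annotations

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_unambiguous(seq: str) -> bool:
    return set(seq) <= set("ACGT")


def validate_iupac(primer: str) -> None:
    bad = set(primer) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters in primer: {sorted(bad)}")


def iupac_mismatches(window: str, primer: str) -> int:
    """Number of window positions outside the primer letter's IUPAC class.

    A plain base in the window matches a degenerate primer letter whenever it
    belongs to that letter's class; any non-ACGT base in the window (e.g. N)
    only matches a primer N.
    """
    mm = 0
    for base, p in zip(window, primer):
        if base not in IUPAC[p] and base != p:
            mm += 1
    return mm


def expand_degenerate(primer: str) -> list[str]:
    """All plain-base strings covered by a degenerate primer (test oracle aid)."""
    outs = [""]
    for p in primer:
        outs = [o + b for o in outs for b in sorted(IUPAC[p])]
    return outs
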