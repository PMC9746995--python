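"""IUPAC nucleotide utilities: degenerate-base matching, primer comparison,
reverse complement.

Degenerate codes are legal in primers only; reference inserts must be plain
A/C/G/T (they come from a single reference assembly).
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

PLAIN_BASES = frozenset("ACGT")


def is_iupac(seq: str) -> bool:
    """True iff every character of ``seq`` is a valid IUPAC nucleotide code."""
    return all(b in IUPAC_SETS for b in seq.upper())


def iupac_match(pattern_base: str, observed_base: str) -> bool:
    """True iff ``observed_base`` (A/C/G/T) is in the expansion set of the
    IUPAC ``pattern_base``.

    Raises ``ValueError`` on an invalid pattern or observed character.
    """
    try:
        expansion = IUPAC_SETS[pattern_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code: {pattern_base!r}") from None
    ob = observed_base.upper()
    if ob not in PLAIN_BASES:
        raise ValueError(f"observed base must be A/C/G/T, got {observed_base!r}")
    return ob in expansion


def match_primer(primer: str, window: str, max_mismatch: int) -> tuple[bool, int]:
    """Compare an IUPAC primer to an observed A/C/G/T window of equal length.

    Returns ``(ok, mismatch_count)`` where ``ok`` is true iff the number of
    positions failing :func:`iupac_match` is at most ``max_mismatch``.
    Characters outside A/C/G/T in the window (e.g. N from the sequencer)
    count as mismatches rather than raising.
    """
    if len(primer) != len(window):
        raise ValueError(
            f"window length {len(window)} != primer length {len(primer)}"
        )
    mismatches = 0
    for p, o in zip(primer.upper(), window.upper()):
        try:
            expansion = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code in primer: {p!r}") from None
        if o not in expansion:
            mismatches += 1
    return mismatches <= max_mismatch, mismatches


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def concretize(seq: str) -> str:
    """Replace every degenerate base by the alphabetically first base of its
    expansion set (deterministic; used to graft primer sequences onto
    synthetic inserts)."""
    return "".join(sorted(IUPAC_SETS[b.upper()])[0] for b in seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))
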