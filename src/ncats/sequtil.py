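"""Small DNA-string helpers shared across modules.

Coordinates are 0-based half-open everywhere inside the package; the
1-based inclusive ``ref:start..end`` dialect appears only at I/O
boundaries (see :mod:`ncats.regions`).
"""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGT")

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence", allow_n: bool = True) -> str:
    """Uppercase *seq* and reject characters outside A/C/G/T (and optionally N)."""
    seq = seq.upper()
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"{what} contains non-DNA characters: {sorted(bad)!r}"
        )
    return seq


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if *seq* (concrete bases) matches the same-length IUPAC *pattern*.

    An ``N`` in *seq* never matches anything narrower than ``N`` in the
    pattern: ambiguity in the subject is treated as unknown, not wild.
    """
    if len(seq) != len(pattern):
        return False
    for s, p in zip(seq, pattern):
        allowed = IUPAC.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern {pattern!r}")
        if s not in allowed:
            return False
    return True
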