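"""IUPAC nucleotide ambiguity codes and strand arithmetic."""

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

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

# Symbol-wise complement: the complement of an ambiguity code is the code
# whose base set is the complement of each member (R={A,G} <-> Y={C,T}).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def validate_iupac(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")


def validate_acgt(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - frozenset("ACGT")
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")


def revcomp(seq: str) -> str:
    """Reverse complement, degenerate codes complemented symbol-wise."""
    validate_iupac(seq)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
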