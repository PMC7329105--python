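"""IUPAC nucleotide alphabet helpers shared across modules."""

from __future__ import annotations

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def possibilities(code: str) -> str:
    """Concrete bases represented by one IUPAC code."""
    try:
        return IUPAC[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code {code!r}") from None


def validate(sequence: str) -> None:
    """Raise ValueError naming the first offending position."""
    if not sequence:
        raise ValueError("empty sequence")
    for i, c in enumerate(sequence):
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i}")


def reverse_complement(sequence: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(sequence))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def compatible(a: str, b: str) -> bool:
    """True when two (possibly ambiguous) codes share a concrete base."""
    return bool(set(IUPAC[a]) & set(IUPAC[b]))


def degeneracy(sequence: str) -> int:
    d = 1
    for c in sequence:
        d *= len(possibilities(c))
    return d
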