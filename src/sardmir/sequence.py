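"""Nucleotide alphabet handling shared by every stage.

All pipeline internals work on uppercase RNA strings over ``{A, C, G, U}``
(``N`` is tolerated in genomic input and never matches anything).  DNA input
is accepted anywhere and transcribed on the fly.
"""

from __future__ import annotations

from .errors import AlphabetError

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_to_rna(seq: str) -> str:
    """Uppercase a DNA/RNA string and transcribe T to U.

    ``N`` is preserved.  Any other character raises :class:`AlphabetError`.
    """
    out = seq.upper().replace("T", "U")
    bad = set(out) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"invalid nucleotide(s) {sorted(bad)!r}; expected A/C/G/T/U/N"
        )
    return out


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_watson_crick(a: str, b: str) -> bool:
    return (a, b) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in (("G", "U"), ("U", "G"))


def can_pair(a: str, b: str) -> bool:
    """True for Watson-Crick or G:U wobble pairs."""
    return is_watson_crick(a, b) or is_wobble(a, b)
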