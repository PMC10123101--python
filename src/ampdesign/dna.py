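"""Small shared DNA helpers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMP)[::-1]


def validate_alphabet(seq: str, allow_n: bool = True) -> None:
    allowed = VALID_BASES if allow_n else frozenset("ACGT")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
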