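"""Small shared sequence helpers (DNA canonical internally, RNA for display)."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to the canonical DNA alphabet (T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase display form with U instead of T."""
    return seq.upper().replace("T", "U")


def check_dna(seq: str, *, allow_empty: bool = True, what: str = "sequence") -> str:
    """Validate a sequence over {A,C,G,T} (U accepted as T); return DNA form.

    Raises ValueError on any other character, including N.
    """
    dna = to_dna(seq)
    if not dna and not allow_empty:
        raise ValueError(f"empty {what}")
    bad = set(dna) - set(DNA_BASES)
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in {what}: {seq!r}")
    return dna
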