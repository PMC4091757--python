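"""Sequence normalization shared by every pipeline stage.

All internal comparison happens in RNA space: DNA input (T) is converted
to U on the way in, and case is folded to upper. `N` is accepted but
flagged by callers that require certainty (exact matching, distance
columns).
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGUN")
_ACCEPTED = frozenset("ACGTUNacgtun")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def normalize_sequence(seq: str) -> str:
    """Canonicalize a nucleotide sequence: uppercase, T->U, nothing else.

    Raises ``ValueError`` on an empty string or any character outside
    ``{A, C, G, T, U, N}`` (either case).
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _ACCEPTED
    if bad:
        raise ValueError(
            f"non-IUPAC nucleotide character(s) {sorted(bad)!r} in sequence"
        )
    return seq.upper().replace("T", "U")


def is_normalized(seq: str) -> bool:
    return bool(seq) and set(seq) <= RNA_ALPHABET


def contains_n(seq: str) -> bool:
    return "N" in seq


def check_protein(seq: str) -> str:
    """Validate a protein sequence (20 standard residues, case-folded)."""
    if not seq:
        raise ValueError("empty protein sequence")
    up = seq.upper()
    bad = set(up) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid character(s) {sorted(bad)!r}")
    return up
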