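"""The fixed 20-letter amino-acid alphabet and its canonical ordering.

All descriptor vectors, schema names (``aac_5`` = cysteine, ...) and matrix
column layouts in this package are defined against this single ordering, so
it lives in one place.
"""

from __future__ import annotations

#: Canonical amino-acid order.  Feature names index into this order 1-based:
#: aac_1 = alanine (A), aac_5 = cysteine (C), aac_11 = leucine (L), ...
ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: Residue -> 0-based index in :data:`ALPHABET`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residue codes that occur in real-world FASTA but are not one of the 20
#: standard amino acids (ambiguity codes, rare residues, stops, gaps).
NONSTANDARD_CODES = frozenset("BZXUOJ*-.")


def encode(residues: str) -> "list[int]":
    """Map a validated residue string to 0-based alphabet indices."""
    return [AA_INDEX[c] for c in residues]
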