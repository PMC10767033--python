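"""Residue alphabet and sequence encoding helpers.

The canonical alphabet is the 20 standard amino acids in lexicographic
order; lexicographic order also fixes argmax tie-breaking wherever a
categorical decision over residues is made.
"""

from __future__ import annotations

import numpy as np

AA20: str = "ACDEFGHIKLMNPQRSTVWY"

_INDEX = {aa: i for i, aa in enumerate(AA20)}


def validate_sequence(sequence: str, alphabet: str = AA20) -> None:
    """Raise ``ValueError`` if *sequence* contains a residue outside *alphabet*."""
    allowed = set(alphabet)
    for pos, aa in enumerate(sequence):
        if aa not in allowed:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos} (alphabet {alphabet!r})"
            )


def one_hot(sequence: str, alphabet: str = AA20) -> np.ndarray:
    """One-hot encode a sequence as an (L, |alphabet|) float matrix."""
    index = _INDEX if alphabet == AA20 else {aa: i for i, aa in enumerate(alphabet)}
    out = np.zeros((len(sequence), len(alphabet)))
    for pos, aa in enumerate(sequence):
        try:
            out[pos, index[aa]] = 1.0
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos} (alphabet {alphabet!r})"
            ) from None
    return out


def one_hot_flat(sequences: list[str], alphabet: str = AA20) -> np.ndarray:
    """Encode equal-length sequences as an (n, L*|alphabet|) design matrix."""
    if not sequences:
        return np.zeros((0, 0))
    length = len(sequences[0])
    for seq in sequences:
        if len(seq) != length:
            raise ValueError(
                f"length mismatch: expected {length}, got {len(seq)} for {seq!r}"
            )
    return np.stack([one_hot(s, alphabet).ravel() for s in sequences])
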