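"""Conjoint-triad (CT) encoding of amino-acid sequences.

The CT scheme groups the 20 standard amino acids into 7 physicochemical
classes (by dipole moment and side-chain volume) and slides a window of
3 residues along the sequence, counting each class triple. With 7 classes
this yields a fixed 7 x 7 x 7 = 343-dimensional representation regardless
of sequence length; counts are normalized to frequencies over the valid
windows so the encoding is length-independent.

Windows containing any non-standard residue letter (B, J, O, U, X, Z) are
skipped rather than remapped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .io import ProteinCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CT_CLASSES",
    "N_CT_FEATURES",
    "load_alphabet",
    "save_alphabet",
    "ct_encode",
    "encode_catalog",
]

#: Standard 7-class conjoint-triad partition of the 20 amino acids:
#: {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}.
DEFAULT_CT_CLASSES: dict[str, int] = {
    "A": 0, "G": 0, "V": 0,
    "I": 1, "L": 1, "F": 1, "P": 1,
    "Y": 2, "M": 2, "T": 2, "S": 2,
    "H": 3, "N": 3, "Q": 3, "W": 3,
    "R": 4, "K": 4,
    "D": 5, "E": 5,
    "C": 6,
}

N_CT_CLASSES = 7
N_CT_FEATURES = N_CT_CLASSES**3  # 343


def _validate_alphabet(class_of: dict[str, int]) -> None:
    letters = set(class_of)
    if letters != set(DEFAULT_CT_CLASSES):
        missing = set(DEFAULT_CT_CLASSES) - letters
        extra = letters - set(DEFAULT_CT_CLASSES)
        raise ValueError(
            f"alphabet must map exactly the 20 standard letters; "
            f"missing={sorted(missing)}, extra={sorted(extra)}"
        )
    classes = set(class_of.values())
    if classes != set(range(N_CT_CLASSES)):
        raise ValueError(
            f"alphabet must use exactly class indices 0..6, got {sorted(classes)}"
        )


def load_alphabet(path: str | Path) -> dict[str, int]:
    """Load a letter -> class-index table from a small key-value text file.

    Each non-comment line holds a single letter and an integer class index,
    whitespace-separated. All 20 standard letters must be present and all
    7 class indices used.
    """
    class_of: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            letter, idx = line.split()
            class_of[letter.upper()] = int(idx)
    _validate_alphabet(class_of)
    return class_of


def save_alphabet(class_of: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for letter in sorted(class_of):
            fh.write(f"{letter}\t{class_of[letter]}\n")


def ct_encode(
    sequence: str, alphabet: dict[str, int] | None = None
) -> np.ndarray:
    """Encode one sequence as a 343-vector of conjoint-triad frequencies.

    For each window of 3 consecutive standard residues with classes
    (c1, c2, c3), the flat feature index c1*49 + c2*7 + c3 is incremented;
    counts are divided by the number of valid windows. Sequences shorter
    than 3, or with no valid window, yield the zero vector (with a logged
    warning), not an error.
    """
    if alphabet is None:
        alphabet = DEFAULT_CT_CLASSES
    _validate_alphabet(alphabet)
    seq = sequence.upper()
    vec = np.zeros(N_CT_FEATURES, dtype=float)
    n_valid = 0
    for i in range(len(seq) - 2):
        window = seq[i : i + 3]
        try:
            c1, c2, c3 = (alphabet[ch] for ch in window)
        except KeyError:
            continue
        vec[c1 * 49 + c2 * 7 + c3] += 1.0
        n_valid += 1
    if n_valid == 0:
        logger.warning(
            "sequence of length %d has no valid triad window; zero vector emitted",
            len(sequence),
        )
        return vec
    return vec / n_valid


def encode_catalog(
    catalog: ProteinCatalog, alphabet: dict[str, int] | None = None
) -> np.ndarray:
    """Encode every catalog entry; row i is ``ct_encode`` of entry i."""
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    return np.vstack([ct_encode(seq, alphabet) for _, seq in catalog])
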