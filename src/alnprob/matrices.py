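"""Built-in substitution score matrices.

HoxD70 is a nucleotide matrix often used for inter-species genome alignment;
"Simple" is the elementary +1/-1 match/mismatch matrix.  Both are indexed by
the DNA alphabet A, C, G, T.
"""

from __future__ import annotations

import numpy as np

from .core import DNA, Alphabet

__all__ = ["HOXD70", "SIMPLE", "BUILTIN_MATRICES", "simple_matrix"]

HOXD70 = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=float,
)

SIMPLE = np.where(np.eye(4, dtype=bool), 1.0, -1.0)

BUILTIN_MATRICES: dict[str, np.ndarray] = {
    "HoxD70": HOXD70,
    "Simple": SIMPLE,
}


def simple_matrix(
    match: float = 1.0, mismatch: float = -1.0, alphabet: Alphabet = DNA
) -> np.ndarray:
    """Match/mismatch matrix over an alphabet (default +1/-1 over ACGT)."""
    k = len(alphabet)
    return np.where(np.eye(k, dtype=bool), float(match), float(mismatch))
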