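"""Small shared helpers: seed derivation and condensed-matrix indexing."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, *names: str) -> int:
    """Derive a stage seed deterministically from a global seed and labels.

    Stable across processes and Python versions (sha256, not hash()); the
    result is always < 2**31 so it is a valid seed everywhere.
    """
    key = "|".join([str(int(global_seed)), *map(str, names)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def condensed_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the upper triangle, in condensed order."""
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju
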