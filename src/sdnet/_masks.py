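"""Precomputed bitmask tables for bipartition scans over k-element sets.

For a set of size k, every nonempty proper subset is encoded as a bit
mask.  The tables (cached per k) hold the boolean membership matrix,
subset sizes, the position of each mask's complement, and per-size index
arrays used to gather submatrices for batched determinant calls.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def mask_tables(k: int):
    """Tables for all 2^k - 2 nonempty proper subsets of {0, ..., k-1}.

    Returns
    -------
    masks : (B,) int array of subset bitmasks, ascending
    bits : (B, k) bool membership matrix
    sizes : (B,) subset cardinalities
    comp_pos : (B,) index into ``masks`` of each mask's complement
    groups : list over cardinality m = 1..k-1 of
        (sel, pidx, cidx) where ``sel`` indexes masks of size m, ``pidx``
        is the (len(sel), m) array of member positions and ``cidx`` the
        (len(sel), k-m) array of non-member positions
    """
    if k < 2:
        raise ValueError("bipartition tables need k >= 2")
    masks = np.arange(1, 2**k - 1, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(k)) & 1).astype(bool)
    sizes = bits.sum(axis=1)
    comp_pos = (2**k - 1 - masks) - 1
    groups = []
    for m in range(1, k):
        sel = np.nonzero(sizes == m)[0]
        _, cols = np.nonzero(bits[sel])
        pidx = cols.reshape(len(sel), m)
        _, cols = np.nonzero(~bits[sel])
        cidx = cols.reshape(len(sel), k - m)
        groups.append((sel, pidx, cidx))
    return masks, bits, sizes, comp_pos, groups


def gather_submatrices(batch: np.ndarray, sel: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Extract ``batch[sel][b][np.ix_(idx[b], idx[b])]`` for all b, vectorized."""
    return batch[sel[:, None, None], idx[:, :, None], idx[:, None, :]]
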