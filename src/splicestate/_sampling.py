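"""Vectorized without-replacement subset sampling shared by the permutation engines.

All empirical nulls in this package are built from uniform random subsets of a
finite pool, drawn without replacement.  For the typical regime (subset size n
much smaller than pool size N) we draw with replacement and reject rows that
contain duplicates, which is exact and fast; when n is a sizable fraction of N
we fall back to per-row partial shuffles.
"""

from __future__ import annotations

import numpy as np

__all__ = ["subset_indices", "subset_means"]


def subset_indices(n_pool: int, n_draw: int, n_sets: int, rng: np.random.Generator) -> np.ndarray:
    """Return an ``(n_sets, n_draw)`` array of indices into a pool of size
    ``n_pool``; each row is a uniform random subset drawn without replacement.
    """
    if not 0 < n_draw <= n_pool:
        raise ValueError(f"subset size {n_draw} invalid for pool of {n_pool}")
    if n_draw == n_pool:
        return np.tile(np.arange(n_pool), (n_sets, 1))
    if n_draw > n_pool // 2 or n_draw * n_draw > n_pool:
        # duplicate rate too high for rejection; argpartition route, chunked
        out = np.empty((n_sets, n_draw), dtype=np.intp)
        chunk = max(1, int(2e7) // max(n_pool, 1))
        for lo in range(0, n_sets, chunk):
            hi = min(lo + chunk, n_sets)
            keys = rng.random((hi - lo, n_pool))
            out[lo:hi] = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
        return out
    idx = rng.integers(0, n_pool, size=(n_sets, n_draw))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), n_draw))


def subset_means(pool: np.ndarray, n_draw: int, n_sets: int, rng: np.random.Generator) -> np.ndarray:
    """Means of ``n_sets`` random subsets of size ``n_draw`` from ``pool``."""
    pool = np.asarray(pool, dtype=float)
    idx = subset_indices(pool.size, n_draw, n_sets, rng)
    return pool[idx].mean(axis=1)
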