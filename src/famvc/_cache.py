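"""Hash-keyed caches for expensive matrix factorizations.

Association scans, model searches and calibration simulations repeatedly fit
variance-component models against the *same* relationship matrices. Caching
the symmetric eigendecomposition (and Cholesky factor) keyed by the matrix
content makes each subsequent fit O(n^2) instead of O(n^3).

Keys are content hashes, so callers do not have to thread decomposition
objects through their APIs; passing the same matrix (by value) hits the
cache. Caches are bounded FIFO.
"""

from __future__ import annotations

import hashlib
from collections import OrderedDict
from typing import Callable, Hashable

import numpy as np

_MAX_ENTRIES = 160


def array_key(a: np.ndarray) -> str:
    """Content hash of a float array (shape-sensitive).

    Large arrays are fingerprinted (strided sample plus global sums) rather
    than fully hashed, so keying a cache by a ~10 MB kinship matrix costs
    ~1 ms instead of ~10 ms per lookup.
    """
    a = np.ascontiguousarray(a)
    h = hashlib.sha1(str(a.shape).encode())
    if a.nbytes <= 1_000_000:
        h.update(a.tobytes())
    else:
        flat = a.reshape(-1)
        step = max(1, flat.size // 65536)
        h.update(flat[::step].tobytes())
        h.update(np.asarray(
            [flat.sum(), np.abs(flat).sum(), flat[::7].sum()], dtype=np.float64
        ).tobytes())
    return h.hexdigest()


class _BoundedCache:
    def __init__(self, maxsize: int = _MAX_ENTRIES):
        self._store: OrderedDict[Hashable, object] = OrderedDict()
        self._maxsize = maxsize

    def get_or_compute(self, key: Hashable, compute: Callable[[], object]):
        if key in self._store:
            self._store.move_to_end(key)
            return self._store[key]
        value = compute()
        self._store[key] = value
        while len(self._store) > self._maxsize:
            self._store.popitem(last=False)
        return value

    def clear(self) -> None:
        self._store.clear()


_eig_cache = _BoundedCache()
_chol_cache = _BoundedCache()


def eigh_cached(K, key: Hashable | None = None):
    """Eigendecomposition ``K = U diag(d) U'`` of a symmetric matrix, cached.

    ``K`` may be the matrix itself or a zero-argument factory returning it
    (so cache hits skip building the matrix entirely). ``key`` overrides the
    content hash — required for factories — and is useful when the caller
    has a cheaper unique key, e.g. a (parent-hash, mixing-weight) tuple.
    """
    if key is None:
        if callable(K):
            raise TypeError("a factory requires an explicit cache key")
        key = array_key(K)

    def compute():
        mat = K() if callable(K) else K
        d, U = np.linalg.eigh(mat)
        return d, U

    return _eig_cache.get_or_compute(("eigh", key), compute)


def cholesky_psd_cached(K: np.ndarray, key: Hashable | None = None) -> np.ndarray:
    """Lower Cholesky factor of a PSD matrix, with a tiny jitter fallback."""
    if key is None:
        key = array_key(K)

    def compute():
        try:
            return np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * np.trace(K) / K.shape[0]
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))

    return _chol_cache.get_or_compute(("chol", key), compute)


def clear_caches() -> None:
    _eig_cache.clear()
    _chol_cache.clear()
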