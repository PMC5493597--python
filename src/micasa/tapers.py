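"""2D Slepian (DPSS) taper construction.

Multitaper spectral estimation windows the data with a family of mutually
orthogonal tapers that maximise spectral energy concentration within a
half-bandwidth ``W``.  For images we build 2D tapers as outer products of
the per-dimension discrete prolate spheroidal sequences (DPSS), ranked by
the product of their 1D concentration eigenvalues — the standard
separable extension of the 1D theory to rectangular domains.  With the
default bandwidth product of 2 per dimension there are three concentrated
sequences per axis, nine candidate products, of which the top M = 7 are
retained by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import windows

__all__ = ["TaperSet", "dpss_1d", "taper_set_2d"]

_MIN_N = 16


def dpss_1d(n: int, bandwidth_product: float) -> tuple[np.ndarray, np.ndarray]:
    """Return the concentrated DPSS family for an ``n``-point dimension.

    Parameters
    ----------
    n
        Sequence length (pixels along one image dimension), >= 16.
    bandwidth_product
        Time-bandwidth parameter ``NW`` (>= 1).  The half-bandwidth is
        ``W = NW / n`` in cycles per sample.

    Returns
    -------
    tapers : (K, n) ndarray
        The ``K = ceil(2 NW) - 1`` leading sequences, each with unit
        energy, mutually orthogonal.
    eigenvalues : (K,) ndarray
        In-band energy concentrations in (0, 1), non-increasing.
    """
    if n < _MIN_N:
        raise ValueError(f"n must be >= {_MIN_N}, got {n}")
    if bandwidth_product < 1.0:
        raise ValueError(f"bandwidth_product must be >= 1, got {bandwidth_product}")
    k = int(np.ceil(2.0 * bandwidth_product)) - 1
    if k >= n:
        raise ValueError(
            f"bandwidth_product {bandwidth_product} too large for n={n}: "
            f"would require {k} sequences"
        )
    tapers, ratios = windows.dpss(
        n, bandwidth_product, Kmax=k, norm=2, return_ratios=True
    )
    tapers = np.atleast_2d(np.asarray(tapers, dtype=float))
    ratios = np.atleast_1d(np.asarray(ratios, dtype=float))
    return tapers, ratios


@dataclass(frozen=True)
class TaperSet:
    """M orthonormal 2D tapers for one image shape.

    Attributes
    ----------
    tapers : (M, rows, cols) ndarray
        Unit-energy, mutually orthogonal 2D windows.
    eigen_products : (M,) ndarray
        Per-taper concentration scores (product of the generating 1D
        eigenvalues), non-increasing.
    index_pairs : (M, 2) ndarray
        The (row-taper, col-taper) index of each retained outer product.
    bandwidth_product : float
        The per-dimension NW the set was built with.
    """

    tapers: np.ndarray
    eigen_products: np.ndarray
    index_pairs: np.ndarray
    bandwidth_product: float

    @property
    def M(self) -> int:
        return self.tapers.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.tapers.shape[1:]


def taper_set_2d(
    rows: int, cols: int, bandwidth_product: float = 2.0, M: int = 7
) -> TaperSet:
    """Build the top-``M`` 2D Slepian tapers for a ``rows x cols`` image.

    Candidates are all outer products ``u_p(y) v_q(x)`` of per-dimension
    DPSS, ranked by the eigenvalue product ``lambda_p * lambda_q`` (ties
    broken lexicographically on ``(p, q)``); the leading ``M`` are kept.
    Orthonormality of the 2D set is inherited from the 1D families.
    """
    u, lam_u = dpss_1d(rows, bandwidth_product)
    v, lam_v = dpss_1d(cols, bandwidth_product)
    n_max = u.shape[0] * v.shape[0]
    if M > n_max:
        raise ValueError(
            f"M={M} exceeds the {n_max} concentrated 2D tapers available at "
            f"bandwidth_product={bandwidth_product} "
            f"({u.shape[0]} x {v.shape[0]} per-dimension sequences)"
        )
    if M < 1:
        raise ValueError("M must be >= 1")

    pairs = [(p, q) for p in range(u.shape[0]) for q in range(v.shape[0])]
    # sort by descending eigenvalue product; lexicographic (p, q) on ties
    pairs.sort(key=lambda pq: (-(lam_u[pq[0]] * lam_v[pq[1]]), pq[0], pq[1]))
    pairs = pairs[:M]

    tapers = np.empty((M, rows, cols), dtype=float)
    products = np.empty(M, dtype=float)
    for m, (p, q) in enumerate(pairs):
        tapers[m] = np.outer(u[p], v[q])
        products[m] = lam_u[p] * lam_v[q]
    return TaperSet(
        tapers=tapers,
        eigen_products=products,
        index_pairs=np.asarray(pairs, dtype=int),
        bandwidth_product=float(bandwidth_product),
    )


@lru_cache(maxsize=64)
def cached_taper_set(rows: int, cols: int, bandwidth_product: float, M: int) -> TaperSet:
    """Per-shape taper cache; sets are reused across images within a run."""
    return taper_set_2d(rows, cols, bandwidth_product, M)
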