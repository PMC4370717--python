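"""Contiguity matrices, Moran's I, correlograms, and permutation tests.

All spatial statistics use binary (non-row-standardised) 0/1 weights:
the aggregation index normalises by the neighbour count explicitly, and
Moran's I divides by the total weight, so row standardisation would only
reweight units, not change the logic.

Moran's I for values x on a weights matrix w is

    I = (n / Σ_ij w_ij) · (Σ_ij w_ij z_i z_j) / (Σ_i z_i²),   z = x − x̄.

Significance is assessed by random permutation of the value labels over
the units (the standard randomisation test for Moran's I, sometimes
loosely called a bootstrap), two-sided on |I| by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Correlogram",
    "build_contiguity",
    "lattice_edges",
    "morans_i",
    "correlogram",
    "morans_i_permutation_test",
]

logger = logging.getLogger(__name__)


def build_contiguity(edges, units) -> np.ndarray:
    """Symmetric 0/1 contiguity matrix from an edge list.

    ``edges`` is an iterable of (unit_a, unit_b) pairs; duplicate and
    reversed pairs are idempotent.  Self-edges and unknown units raise.
    """
    units = list(units)
    index = {u: i for i, u in enumerate(units)}
    if len(index) != len(units):
        raise ValueError("duplicate unit ids")
    w = np.zeros((len(units), len(units)))
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-edge on unit {a!r}")
        try:
            i, j = index[a], index[b]
        except KeyError as err:
            raise ValueError(f"edge endpoint {err.args[0]!r} not in unit list") from None
        w[i, j] = w[j, i] = 1.0
    return w


def lattice_edges(rows: int, cols: int) -> list[tuple[int, int]]:
    """Rook-contiguity edges of a rows × cols lattice, units numbered row-major."""
    if rows <= 0 or cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    edges = []
    for r in range(rows):
        for c in range(cols):
            u = r * cols + c
            if c + 1 < cols:
                edges.append((u, u + 1))
            if r + 1 < rows:
                edges.append((u, u + cols))
    return edges


def _check_morans_inputs(x: np.ndarray, w: np.ndarray) -> None:
    if x.ndim != 1 or w.shape != (x.size, x.size):
        raise ValueError("values and weights matrix must align")
    if w.sum() == 0:
        raise ValueError("weights matrix has no nonzero entries")
    if np.allclose(x, x[0]):
        raise ValueError("Moran's I undefined for zero-variance values")


def morans_i(values, w) -> float:
    """Global Moran's I of ``values`` under the weights matrix ``w``."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(w, dtype=float)
    _check_morans_inputs(x, w)
    z = x - x.mean()
    return float(x.size / w.sum() * (z @ w @ z) / (z @ z))


@dataclass
class Correlogram:
    """Moran's I per distance class, with the class of maximal I."""

    class_edges: np.ndarray          # (k+1,) increasing bin edges, km
    morans: np.ndarray               # (k,) I per class, nan where no pair
    n_pairs: np.ndarray              # (k,) pair count per class
    argmax_class: int                # index of the class with maximal I
    flat: bool = field(default=False)  # True when all |I| are small (no structure)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.class_edges) <= 0):
            raise ValueError("distance class edges must be strictly increasing")


def correlogram(values, centroids, class_edges, *, flat_threshold: float = 0.1) -> Correlogram:
    """Moran's I correlogram over distance classes of centroid separation.

    For each class (lo, hi] a binary weights matrix connects unit pairs
    whose centroid distance falls in the class; Moran's I is computed per
    class and the class with maximal I reported.  Empty classes yield a
    missing I (logged).  When every defined |I| is below
    ``flat_threshold`` the correlogram is flagged flat — there is no
    detectable spatial structure and the argmax is not meaningful.
    """
    x = np.asarray(values, dtype=float)
    pts = np.asarray(centroids, dtype=float)
    edges = np.asarray(class_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least one distance class (two edges)")
    dist = squareform(pdist(pts))
    morans = np.full(edges.size - 1, np.nan)
    n_pairs = np.zeros(edges.size - 1, dtype=int)
    for k in range(edges.size - 1):
        w = ((dist > edges[k]) & (dist <= edges[k + 1])).astype(float)
        np.fill_diagonal(w, 0.0)
        n_pairs[k] = int(w.sum()) // 2
        if n_pairs[k] == 0:
            logger.info("distance class (%g, %g] km has no pair; I missing", edges[k], edges[k + 1])
            continue
        morans[k] = morans_i(x, w)
    if np.isnan(morans).all():
        raise ValueError("no distance class contains any pair")
    argmax = int(np.nanargmax(morans))
    flat = bool(np.nanmax(np.abs(morans)) < flat_threshold)
    if flat:
        logger.warning("flat correlogram: max |I| = %.3f < %.3f, argmax class unstable",
                       np.nanmax(np.abs(morans)), flat_threshold)
    return Correlogram(edges, morans, n_pairs, argmax, flat)


def morans_i_permutation_test(values, w, n_perm: int = 999, seed: int | None = None):
    """Permutation test of Moran's I; returns ``(I_obs, p_value)``.

    Value labels are randomly permuted over the units ``n_perm`` times
    and the two-sided p-value computed as
    ``(1 + #{|I*| ≥ |I_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = np.asarray(values, dtype=float)
    w = np.asarray(w, dtype=float)
    _check_morans_inputs(x, w)
    i_obs = morans_i(x, w)
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    denom = z @ z
    scale = x.size / w.sum()
    # batch the permuted quadratic forms: rows of Z are permuted z-vectors
    perms = np.array([rng.permutation(x.size) for _ in range(n_perm)])
    Z = z[perms]
    i_perm = scale * np.einsum("ij,ij->i", Z @ w, Z) / denom
    p = (1.0 + np.sum(np.abs(i_perm) >= abs(i_obs))) / (n_perm + 1.0)
    return i_obs, float(p)
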