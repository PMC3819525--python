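"""Isotonic-regression decomposition of a GP map.

The monotone component G_M of a map G is its least-squares projection onto
the closed convex cone of maps that respect every cover edge of the product
partial order on genotype space (G(..11..) <= G(..12..) <= G(..22..) at
every locus in every background).  Uniqueness follows from strict convexity
of the objective.  The residual G_N = G - G_M satisfies sum_g G_M(g) G_N(g)
= 0 and sum_g G_N(g) = 0, so var(G) = var(G_M) + var(G_N) and

    R2_mono = var(G_M) / var(G)

measures how much of the map's variation a fully order-preserving map can
carry.  R2_mono is 1 exactly for monotone maps but stays strictly positive
even for purely overdominant or purely epistatic maps.

The projection is computed exactly via Moreau's decomposition: with C the
(edges x genotypes) difference matrix (row e: +1 on the upper, -1 on the
lower genotype), the cone is K = {x : Cx >= 0} and

    proj_K(g) = g + C' lam,   lam = argmin_{lam >= 0} ||g + C' lam||^2,

a nonnegative least-squares problem solved by the (finite, exact)
Lawson-Hanson active-set algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gpmap import GPMap, Orientation, PartialOrder, orient_alleles, partial_order_covers

__all__ = ["MonotoneDecomposition", "cover_matrix", "isotonic_fit", "decompose_monotone"]

DEFAULT_TOL = 1e-10


def _nnls(A: np.ndarray, b: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Lawson-Hanson active-set solve of min ||A x - b|| subject to x >= 0.

    Finite and exact up to least-squares round-off; the passive set grows
    by the most violated dual coordinate and shrinks by the standard
    feasibility line search.
    """
    m, n = A.shape
    if max_iter is None:
        max_iter = 10 * n
    x = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    w = A.T @ b
    tol = 10 * np.finfo(float).eps * np.linalg.norm(A, 1) * max(m, n)
    for _ in range(max_iter):
        if passive.all() or np.max(w[~passive], initial=-np.inf) <= tol:
            break
        free = np.flatnonzero(~passive)
        passive[free[np.argmax(w[free])]] = True
        while True:
            idx = np.flatnonzero(passive)
            z, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            if np.min(z, initial=np.inf) > 0:
                x[:] = 0.0
                x[idx] = z
                break
            neg = z <= 0
            alpha = np.min(x[idx][neg] / (x[idx][neg] - z[neg]))
            x[idx] += alpha * (z - x[idx])
            passive[idx[x[idx] <= tol]] = False
            x[~passive] = 0.0
        w = A.T @ (b - A @ x)
    return x


def cover_matrix(order: PartialOrder) -> np.ndarray:
    """Dense difference matrix C with one row x_upper - x_lower per cover edge."""
    n = 3**order.n_loci
    C = np.zeros((len(order.cover_edges), n))
    for row, (lo, hi) in enumerate(order.cover_edges):
        C[row, lo] = -1.0
        C[row, hi] = 1.0
    return C


def isotonic_fit(
    gpmap: GPMap,
    order: PartialOrder | None = None,
    tol: float = DEFAULT_TOL,
    weights: np.ndarray | None = None,
) -> GPMap:
    """Euclidean (or weighted) projection of a GP map onto the monotone cone.

    Parameters
    ----------
    gpmap
        Input map; the caller is responsible for allele orientation
        (see :func:`decompose_monotone`, which orients by default).
    order
        Partial order to fit against; defaults to the full product order.
    tol
        Maximum tolerated cover-edge violation in the fit.
    weights
        Optional positive observation weights; uniform by default.  The
        decomposition in use here is unweighted.
    """
    if order is None:
        order = partial_order_covers(gpmap.n_loci)
    g_raw = gpmap.values
    C = cover_matrix(order)
    # centre and scale: the constant vector lies in the cone's lineality
    # space and the cone is invariant under positive scaling, so the
    # projection commutes with both; this keeps the NNLS well conditioned.
    shift = float(g_raw.mean())
    scale = float(np.max(np.abs(g_raw - shift)))
    if scale == 0.0:
        scale = 1.0
    g = (g_raw - shift) / scale
    if weights is None:
        lam = _nnls(C.T, -g)
        fit = g + C.T @ lam
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != g.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per genotype")
        sw = np.sqrt(w)
        # projection in the sqrt(w)-scaled coordinates
        lam = _nnls((C / sw).T, -sw * g)
        fit = g + (C.T @ lam) / w
    fit = fit * scale + shift
    viol = float(np.max(-(C @ fit), initial=0.0))
    if viol > tol:
        raise RuntimeError(f"isotonic fit violates order by {viol:.3g} > tol={tol:.3g}")
    return GPMap(n_loci=gpmap.n_loci, values=fit)


@dataclass(frozen=True)
class MonotoneDecomposition:
    """Orthogonal split G = G_M + G_N with r2_mono = var(G_M)/var(G)."""

    monotone: GPMap       # G_M
    residual: GPMap       # G_N
    r2_mono: float
    orientation: Orientation | None

    @property
    def reconstructed(self) -> np.ndarray:
        return self.monotone.values + self.residual.values


def decompose_monotone(
    gpmap: GPMap,
    tol: float = DEFAULT_TOL,
    orient: bool = True,
    weights: np.ndarray | None = None,
) -> MonotoneDecomposition:
    """Decompose a GP map into monotone and non-monotone components.

    Alleles are oriented first by default (minimal homozygote to 11...11):
    unlike the substitution-effect degree of monotonicity, R2_mono is not
    invariant to allele relabelling, so the orientation convention is part
    of the measure.  A flat input has no defined r2_mono (NaN).
    """
    work, orientation = orient_alleles(gpmap) if orient else (gpmap, None)
    fit = isotonic_fit(work, tol=tol, weights=weights)
    residual = GPMap(n_loci=work.n_loci, values=work.values - fit.values)
    var_g = float(np.var(work.values))
    r2 = float(np.var(fit.values)) / var_g if var_g > 0 else math.nan
    return MonotoneDecomposition(
        monotone=fit, residual=residual, r2_mono=r2, orientation=orientation
    )
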