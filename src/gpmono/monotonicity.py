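"""Degree of monotonicity of a GP map from single-allele substitution effects.

For locus k with background g^(k) fixed, the two substitution effects are

    s2 = G(..12..) - G(..11..)   (first 2-allele added)
    s1 = G(..22..) - G(..12..)   (second 2-allele added)

The map is order-preserving w.r.t. locus k iff every effect is >= 0.  With
P_k the sum of positive effects and N_k the summed magnitude of negative
effects (T_k = P_k + N_k), the per-locus degree of monotonicity is

    m_k = |P_k - N_k| / T_k,

which is 1 exactly when all nonzero effects share a sign and 0 when the
positive and negative effects balance.  The overall degree of monotonicity
is the T_k-weighted mean of the m_k, so loci with larger total substitution
effects dominate.  Both m_k and m are invariant to allele relabelling and to
positive affine transformation of the trait scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gpmap import GPMap, orient_alleles

__all__ = [
    "LocusMonotonicity",
    "MonotonicityReport",
    "substitution_effects",
    "locus_monotonicity",
    "degree_of_monotonicity",
    "is_monotone_locus",
    "order_breaking_count",
    "default_zero_tol",
]


def default_zero_tol(gpmap: GPMap) -> float:
    """Default tolerance below which an effect counts as exactly zero.

    Scaled to the value range (1e-9 * (max - min)) so that numerically
    derived maps (e.g. ODE equilibria) are not flagged as order-breaking by
    solver noise.
    """
    return 1e-9 * float(np.ptp(gpmap.values))


def substitution_effects(gpmap: GPMap, locus: int) -> np.ndarray:
    """All 2*3**(N-1) single-allele substitution effects at a locus (1-based).

    Returns a flat array ordered by genotypic background (canonical index
    order), with the lower substitution (11->12) before the upper one
    (12->22) within each background.
    """
    n = gpmap.n_loci
    if not 1 <= locus <= n:
        raise IndexError(f"locus {locus} out of range 1..{n}")
    shaped = gpmap.values.reshape(3 ** (locus - 1), 3, 3 ** (n - locus))
    # move the locus axis last, backgrounds in canonical order along the front
    per_bg = np.moveaxis(shaped, 1, -1).reshape(-1, 3)
    effects = np.diff(per_bg, axis=1)  # columns: (s2, s1) per background
    return effects.reshape(-1)


@dataclass(frozen=True)
class LocusMonotonicity:
    locus: int
    effects: np.ndarray
    positive_sum: float  # P_k
    negative_sum: float  # N_k (summed magnitudes)
    total: float         # T_k
    m: float             # |P_k - N_k| / T_k, NaN if T_k == 0
    monotone: bool


@dataclass(frozen=True)
class MonotonicityReport:
    per_locus: tuple
    m: float
    order_breaking_count: int
    zero_tol: float
    flat: bool

    def __str__(self):
        lines = [f"degree of monotonicity m = {self.m:.6g}"]
        for lm in self.per_locus:
            lines.append(
                f"  locus {lm.locus}: m_k={lm.m:.6g} P={lm.positive_sum:.6g} "
                f"N={lm.negative_sum:.6g} T={lm.total:.6g} "
                f"{'monotone' if lm.monotone else 'order-breaking'}"
            )
        return "\n".join(lines)


def locus_monotonicity(
    gpmap: GPMap, locus: int, zero_tol: float | None = None
) -> LocusMonotonicity:
    """Sign-split substitution-effect sums and m_k for one locus.

    Effects with magnitude <= zero_tol are treated as exactly zero and
    excluded from both sign sets.  A locus with no nonzero effects carries
    no variation: T_k = 0 and m_k is NaN.
    """
    if zero_tol is None:
        zero_tol = default_zero_tol(gpmap)
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    s = substitution_effects(gpmap, locus)
    pos = float(s[s > zero_tol].sum())
    neg = float(-s[s < -zero_tol].sum())
    total = pos + neg
    m = abs(pos - neg) / total if total > 0 else math.nan
    monotone = neg == 0.0
    return LocusMonotonicity(
        locus=locus,
        effects=s,
        positive_sum=pos,
        negative_sum=neg,
        total=total,
        m=m,
        monotone=monotone,
    )


def degree_of_monotonicity(
    gpmap: GPMap,
    zero_tol: float | None = None,
    orient: bool = True,
) -> tuple[float, MonotonicityReport]:
    """Overall degree of monotonicity m and full per-locus report.

    m is the T_k-weighted mean of the per-locus m_k over loci with T_k > 0.
    A fully flat map has no defined m (returned as NaN, flagged in the
    report).  Orientation affects only the boolean order-breaking flags,
    never m_k or m; by default alleles are oriented so that the all-1
    homozygote has the minimal homozygote value.
    """
    if zero_tol is None:
        zero_tol = default_zero_tol(gpmap)
    work = orient_alleles(gpmap)[0] if orient else gpmap
    per_locus = tuple(
        locus_monotonicity(work, k, zero_tol) for k in range(1, work.n_loci + 1)
    )
    total = sum(lm.total for lm in per_locus)
    if total > 0:
        m = sum(lm.m * lm.total for lm in per_locus if lm.total > 0) / total
        flat = False
    else:
        m = math.nan
        flat = True
    breaking = sum(1 for lm in per_locus if lm.total > 0 and not lm.monotone)
    report = MonotonicityReport(
        per_locus=per_locus,
        m=m,
        order_breaking_count=breaking,
        zero_tol=zero_tol,
        flat=flat,
    )
    return m, report


def is_monotone_locus(
    gpmap: GPMap, locus: int, zero_tol: float | None = None, orient: bool = True
) -> bool:
    """True iff every locus-k substitution effect is >= -zero_tol.

    Non-strict inequalities keep complete dominance and complete magnitude
    epistasis in the order-preserving class.
    """
    work = orient_alleles(gpmap)[0] if orient else gpmap
    return locus_monotonicity(work, locus, zero_tol).monotone


def order_breaking_count(
    gpmap: GPMap, zero_tol: float | None = None, orient: bool = True
) -> int:
    """Number of loci (0..N) for which the map breaks the partial order."""
    work = orient_alleles(gpmap)[0] if orient else gpmap
    return sum(
        not locus_monotonicity(work, k, zero_tol).monotone
        for k in range(1, work.n_loci + 1)
    )
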