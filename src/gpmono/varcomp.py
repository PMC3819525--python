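"""Orthogonal decomposition of a GP map into additive, dominance and
epistatic components under equal genotype frequencies.

With every genotype at frequency 1/3**N, the NOIA statistical formulation,
its functional formulation and the unweighted regression model coincide.
The genotypic values are regressed on a fully orthogonal basis built from
per-locus contrasts (indexed by 2-allele content 0, 1, 2):

    mean      (1,  1,  1)
    additive  (-1, 0,  1)
    dominance (-1, 2, -1)

Kronecker products of these across loci span the full 3**N-dimensional
space, so the regression is exact: the map is reconstructed by summing all
components, the genetic variance V_G equals the population variance of the
genotypic values, and each term contributes an independent slice of it.
V_A sums the single-locus additive terms; V_A/V_G measures how well a
purely additive map describes G.  Contrast scaling is immaterial because
component variances are projection variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from itertools import product

import numpy as np

from .gpmap import GPMap

__all__ = ["VarianceComponents", "design_matrix", "term_labels", "variance_components"]

_LOCUS_BASIS = np.array(
    [
        [1.0, -1.0, -1.0],
        [1.0, 0.0, 2.0],
        [1.0, 1.0, -1.0],
    ]
)  # rows: 2-allele content 0,1,2; columns: mean, additive, dominance


def design_matrix(n_loci: int) -> np.ndarray:
    """3**N x 3**N orthogonal design for the equal-frequency decomposition.

    Column j is the Kronecker product across loci (locus 1 most
    significant, matching the canonical genotype order) of the per-locus
    columns selected by the base-3 digits of j.  Columns are mutually
    orthogonal under the uniform inner product.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return reduce(np.kron, [_LOCUS_BASIS] * n_loci)


def term_labels(n_loci: int) -> list[str]:
    """Term label per design column, e.g. 'a1', 'd2', 'a1:d2', '1' = mean."""
    letters = {0: None, 1: "a", 2: "d"}
    labels = []
    for combo in product((0, 1, 2), repeat=n_loci):
        parts = [
            f"{letters[c]}{k + 1}" for k, c in enumerate(combo) if c != 0
        ]
        labels.append(":".join(parts) if parts else "1")
    return labels


@dataclass(frozen=True)
class VarianceComponents:
    """Per-term effects and variance slices of an equal-frequency decomposition."""

    n_loci: int
    labels: tuple
    effects: np.ndarray        # regression coefficient per term
    variances: np.ndarray      # variance contributed per term (0 for the mean)
    orders: np.ndarray         # number of loci involved per term
    V_A: float
    V_G: float

    @property
    def ratio(self) -> float:
        """V_A / V_G, NaN for a flat map."""
        return self.V_A / self.V_G if self.V_G > 0 else math.nan

    @property
    def V_D(self) -> float:
        """Summed single-locus dominance variance."""
        single = self.orders == 1
        dom = np.array([lab.startswith("d") for lab in self.labels])
        return float(self.variances[single & dom].sum())

    def variance_by_order(self) -> dict:
        """Aggregate variance per interaction order (1 = single locus, ...)."""
        return {
            int(o): float(self.variances[self.orders == o].sum())
            for o in range(1, self.n_loci + 1)
        }


def variance_components(gpmap: GPMap) -> VarianceComponents:
    """Decompose a GP map under equal genotype frequencies (1/3**N).

    Effects are exact orthogonal projections of the genotypic values onto
    the design columns; the variance of a term is its coefficient squared
    times the column's population variance.  The non-mean variances sum to
    V_G = var(G); V_A collects the single-locus additive terms.
    """
    X = design_matrix(gpmap.n_loci)
    g = gpmap.values
    col_ss = np.einsum("ij,ij->j", X, X)
    effects = (X.T @ g) / col_ss
    n = g.size
    col_var = col_ss / n  # columns other than the mean have zero mean
    variances = effects**2 * col_var
    variances[0] = 0.0
    labels = term_labels(gpmap.n_loci)
    orders = np.array([0 if lab == "1" else lab.count(":") + 1 for lab in labels])
    additive_single = np.array(
        [lab.startswith("a") and ":" not in lab for lab in labels]
    )
    v_a = float(variances[additive_single & (orders == 1)].sum())
    v_g = float(np.var(g))
    return VarianceComponents(
        n_loci=gpmap.n_loci,
        labels=tuple(labels),
        effects=effects,
        variances=variances,
        orders=orders,
        V_A=v_a,
        V_G=v_g,
    )
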