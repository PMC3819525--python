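"""Core genotype-phenotype map data model.

A GP map assigns a real genotypic value (mean trait value) to each of the
3**N genotypes over N biallelic diploid loci.  Genotypes are encoded by
their per-locus 2-allele content ``c_k`` in {0, 1, 2} (the number of
alleles indexed "2" at locus k), and stored in the canonical base-3 order
with locus 1 most significant: 1111, 1112, 1122, 1211, ..., 2222.

The 2-allele content induces the product partial order on genotype space
(11 < 12 < 22 at each locus, backgrounds fixed), which is the order both
monotonicity measures refer to.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GPMap",
    "PartialOrder",
    "Orientation",
    "genotype_index",
    "genotype_counts",
    "genotype_label",
    "label_to_counts",
    "partial_order_covers",
    "orient_alleles",
    "apply_orientation",
    "catalog_map",
    "catalog_names",
    "random_gpmap",
    "rearrange_monotone",
]


class InvalidGenotypeError(ValueError):
    """Raised for allele counts outside {0, 1, 2} or malformed labels."""


class CatalogError(KeyError):
    """Raised for an unknown catalog map name."""


@dataclass(frozen=True)
class GPMap:
    """Genotypic values over the full 3**N genotype space.

    Parameters
    ----------
    n_loci
        Number of biallelic loci N.
    values
        Array of 3**N finite genotypic values in canonical order.
    """

    n_loci: int
    values: np.ndarray

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (3**self.n_loci,):
            raise ValueError(
                f"expected {3**self.n_loci} genotypic values, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("genotypic values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n_genotypes(self) -> int:
        return 3**self.n_loci

    @property
    def labels(self) -> list[str]:
        """Genotype strings like '1211' in canonical order."""
        return [genotype_label(genotype_counts(i, self.n_loci)) for i in range(self.n_genotypes)]

    def value(self, counts) -> float:
        return float(self.values[genotype_index(counts)])

    def is_flat(self, tol: float = 0.0) -> bool:
        return float(np.ptp(self.values)) <= tol


@dataclass(frozen=True)
class PartialOrder:
    """Cover relation of the product order on the 3**N genotype space.

    ``cover_edges`` holds (lower, upper) canonical-index pairs; each pair
    differs at exactly one locus by one step of 2-allele content.
    """

    n_loci: int
    cover_edges: tuple = field(repr=False)


@dataclass(frozen=True)
class Orientation:
    """Per-locus allele-label swaps (True = labels 1 and 2 interchanged)."""

    flips: tuple

    @property
    def is_identity(self) -> bool:
        return not any(self.flips)


def genotype_index(counts) -> int:
    """Canonical index of a genotype given its per-locus 2-allele counts.

    index = sum_k c_k * 3**(N-k), locus 1 most significant, matching the
    listing order 1111, 1112, 1122, 1211, ..., 2222.
    """
    idx = 0
    for c in counts:
        if c not in (0, 1, 2):
            raise InvalidGenotypeError(f"allele count {c!r} not in {{0, 1, 2}}")
        idx = 3 * idx + c
    return idx


def genotype_counts(index: int, n_loci: int) -> tuple:
    """Inverse of :func:`genotype_index`."""
    if not 0 <= index < 3**n_loci:
        raise InvalidGenotypeError(f"index {index} out of range for N={n_loci}")
    counts = []
    for k in range(n_loci):
        counts.append(index // 3 ** (n_loci - 1 - k) % 3)
    return tuple(counts)


_COUNT_TO_PAIR = {0: "11", 1: "12", 2: "22"}
_PAIR_TO_COUNT = {"11": 0, "12": 1, "21": 1, "22": 2}


def genotype_label(counts) -> str:
    """Genotype string for per-locus counts, e.g. (1, 0) -> '1211'."""
    return "".join(_COUNT_TO_PAIR[c] for c in counts)


def label_to_counts(label: str) -> tuple:
    """Parse a genotype string of 2N digits from {1,2} into counts."""
    if len(label) % 2 or not label:
        raise InvalidGenotypeError(f"genotype string {label!r} must have even length")
    counts = []
    for i in range(0, len(label), 2):
        pair = label[i : i + 2]
        if pair not in _PAIR_TO_COUNT:
            raise InvalidGenotypeError(f"bad locus genotype {pair!r} in {label!r}")
        counts.append(_PAIR_TO_COUNT[pair])
    return tuple(counts)


def partial_order_covers(n_loci: int) -> PartialOrder:
    """All cover edges of the product order (2N * 3**(N-1) of them).

    Edges are emitted in deterministic order: by lower-genotype canonical
    index, then by locus.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    edges = []
    for idx in range(3**n_loci):
        counts = genotype_counts(idx, n_loci)
        for k in range(n_loci):
            if counts[k] < 2:
                upper = idx + 3 ** (n_loci - 1 - k)
                edges.append((idx, upper))
    return PartialOrder(n_loci=n_loci, cover_edges=tuple(edges))


def apply_orientation(gpmap: GPMap, orientation: Orientation) -> GPMap:
    """Relabel alleles at the flipped loci (an involution on maps)."""
    n = gpmap.n_loci
    if len(orientation.flips) != n:
        raise ValueError("orientation length does not match n_loci")
    new_values = np.empty_like(gpmap.values)
    for idx in range(gpmap.n_genotypes):
        counts = genotype_counts(idx, n)
        src = tuple(2 - c if f else c for c, f in zip(counts, orientation.flips))
        new_values[idx] = gpmap.values[genotype_index(src)]
    return GPMap(n_loci=n, values=new_values)


def orient_alleles(gpmap: GPMap) -> tuple[GPMap, Orientation]:
    """Relabel alleles so the all-1 homozygote has the minimal homozygote value.

    Among the 2**N fully homozygous genotypes the one with minimal value is
    mapped to 11...11 by per-locus allele swaps.  Ties are broken by fewest
    flips, then lexicographically smallest flip pattern.
    """
    n = gpmap.n_loci
    best = None
    for flips in itertools.product((False, True), repeat=n):
        counts = tuple(2 if f else 0 for f in flips)
        val = gpmap.values[genotype_index(counts)]
        key = (val, sum(flips), flips)
        if best is None or key < best:
            best = key
    orientation = Orientation(flips=best[2])
    return apply_orientation(gpmap, orientation), orientation


# ---------------------------------------------------------------------------
# Catalog of classical two-locus maps.
#
# Each map is expressed through per-locus gene action or a classical
# epistasis pattern, normalised to the [0, 1] range.  Exact scaling is
# immaterial: both monotonicity measures and V_A/V_G are scale-free.
# ---------------------------------------------------------------------------

def _per_locus_sum(g1, g2):
    """Two-locus map as a sum of single-locus maps (tuples indexed by count)."""
    return [0.5 * (g1[c1] + g2[c2]) for c1 in range(3) for c2 in range(3)]


_ADD = (0.0, 0.5, 1.0)        # additive gene action
_PD = (0.0, 0.75, 1.0)        # partial dominance of the 2 allele
_CD = (0.0, 1.0, 1.0)         # complete dominance
_OD = (0.0, 1.0, 0.0)         # pure overdominance
_A_CONTRAST = (-1.0, 0.0, 1.0)
_D_CONTRAST = (-1.0, 2.0, -1.0)


def _catalog_values(name: str):
    if name == "A":
        return _per_locus_sum(_ADD, _ADD)
    if name == "PD":
        return _per_locus_sum(_PD, _PD)
    if name == "CD":
        return _per_locus_sum(_CD, _CD)
    if name == "OD":
        return _per_locus_sum(_OD, _OD)
    if name == "DD":
        # duplicate dominant epistasis (15:1): only the double 11-homozygote
        # lacks a dominant allele at both loci
        return [0.0 if (c1, c2) == (0, 0) else 1.0 for c1 in range(3) for c2 in range(3)]
    if name == "DR":
        # duplicate recessive genes (9:7): a dominant allele needed at both loci
        return [1.0 if c1 >= 1 and c2 >= 1 else 0.0 for c1 in range(3) for c2 in range(3)]
    if name == "RE":
        # recessive epistasis (9:3:4): 11 at locus 1 masks locus 2
        vals = []
        for c1 in range(3):
            for c2 in range(3):
                if c1 == 0:
                    vals.append(0.0)
                else:
                    vals.append(0.5 if c2 == 0 else 1.0)
        return vals
    if name == "AxA":
        return [
            ((_A_CONTRAST[c1] * _A_CONTRAST[c2]) + 1.0) / 2.0
            for c1 in range(3)
            for c2 in range(3)
        ]
    if name == "DxD":
        return [
            ((_D_CONTRAST[c1] * _D_CONTRAST[c2]) + 2.0) / 6.0
            for c1 in range(3)
            for c2 in range(3)
        ]
    if name == "AxD":
        return [
            ((_A_CONTRAST[c1] * _D_CONTRAST[c2]) + 2.0) / 4.0
            for c1 in range(3)
            for c2 in range(3)
        ]
    if name == "mouseweight":
        # 10-week body weight (grams) for a two-locus mouse F2 cross,
        # canonical order 1111, 1112, 1122, 1211, 1212, 1222, 2211, 2212, 2222
        return [31.23, 34.13, 33.82, 34.89, 35.90, 36.53, 34.12, 37.95, 36.84]
    raise CatalogError(
        f"unknown catalog map {name!r}; valid names: {', '.join(catalog_names())}"
    )


def catalog_names() -> tuple:
    return ("A", "PD", "CD", "DD", "DR", "RE", "OD", "AxA", "DxD", "AxD", "mouseweight")


def catalog_map(name: str) -> GPMap:
    """Return a canonical two-locus GP map by name.

    Monotone examples: additive (A), partial dominance (PD), complete
    dominance (CD), duplicate dominant (DD), duplicate recessive (DR),
    recessive epistasis (RE).  Non-monotone: overdominance (OD) and the
    pure epistasis maps AxA, DxD, AxD.  'mouseweight' is the empirical
    two-locus mouse body-weight map (values in grams).
    """
    return GPMap(n_loci=2, values=np.array(_catalog_values(name)))


def random_gpmap(n_loci: int, rng: np.random.Generator) -> GPMap:
    """Random GP map: 3**N genotypic values i.i.d. uniform on [0, 1)."""
    return GPMap(n_loci=n_loci, values=rng.random(3**n_loci))


def rearrange_monotone(gpmap: GPMap, locus: int) -> GPMap:
    """Sort genotypic values within each background of ``locus`` (1-based).

    The three values sharing a background are reordered ascending in the
    2-allele content of the chosen locus, so the output is order-preserving
    with respect to that locus while keeping the multiset of values.
    """
    n = gpmap.n_loci
    if not 1 <= locus <= n:
        raise IndexError(f"locus {locus} out of range 1..{n}")
    stride = 3 ** (n - locus)
    vals = gpmap.values.copy()
    shaped = vals.reshape(3 ** (locus - 1), 3, 3 ** (n - locus))
    shaped.sort(axis=1)
    return GPMap(n_loci=n, values=shaped.reshape(-1))
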