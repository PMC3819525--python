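"""Enumeration and classification of 3-gene regulatory network motifs.

A network over genes X1, X2, X3 is a 3x3 signed connectivity matrix A with
A[k,l] in {-1, 0, 1} (X_l represses / ignores / activates X_k) and at most
two regulators per gene (row).  The study space keeps networks where X3 is
downstream of both X1 and X2 — directly (A31*A32 != 0) or one directly and
the other through the remaining gene (A31*A12 != 0 or A32*A21 != 0) — and
collapses the X1<->X2 relabelling symmetry to one representative per orbit.

Feedback and feedforward structure is read off A as signed loop products:
nonzero means the loop is present, the sign is the loop's sign.  A motif is
classed by (i) whether it contains an incoherent feedforward onto X3
(negative FFL product) and (ii) whether it contains any positive feedback
loop, autoregulation included.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np

__all__ = [
    "LoopProfile",
    "MotifClass",
    "enumerate_all",
    "filter_downstream",
    "reduce_symmetry",
    "swap_x1_x2",
    "loop_products",
    "classify",
    "is_weakly_connected",
    "motif_table",
]

FL_NAMES = ("FL1", "FL2", "FL3", "FL12", "FL13", "FL23", "FL123", "FL213")
FFL_NAMES = ("FFL32", "FFL31")
CLASS_LABELS = ("both", "ffl_only", "fb_only", "neither")


def _rows():
    """The 19 sign patterns for one row (<= 2 nonzero entries)."""
    return [r for r in product((-1, 0, 1), repeat=3) if sum(v != 0 for v in r) <= 2]


def enumerate_all() -> list[np.ndarray]:
    """All 6859 connectivity matrices, deterministic lexicographic order."""
    rows = _rows()
    return [np.array(rs, dtype=int) for rs in product(rows, repeat=3)]


def _downstream_ok(A: np.ndarray) -> bool:
    return bool(
        A[2, 0] * A[2, 1] != 0 or A[2, 0] * A[0, 1] != 0 or A[2, 1] * A[1, 0] != 0
    )


def filter_downstream(matrices) -> list[np.ndarray]:
    """Keep matrices where X3 is downstream of both X1 and X2 (3724 of 6859)."""
    return [A for A in matrices if _downstream_ok(A)]


def swap_x1_x2(A: np.ndarray) -> np.ndarray:
    """Relabel genes X1 and X2 (simultaneous row and column exchange)."""
    perm = [1, 0, 2]
    return A[np.ix_(perm, perm)]


def reduce_symmetry(matrices) -> list[np.ndarray]:
    """One representative per X1<->X2 orbit (1881 from 3724).

    The representative is the orbit member with the lexicographically
    smallest row-major flattening; swap-invariant matrices appear once.
    """
    out = []
    for A in matrices:
        if tuple(A.ravel()) <= tuple(swap_x1_x2(A).ravel()):
            out.append(A)
    return out


@dataclass(frozen=True)
class LoopProfile:
    """Signed feedback (FL) and feedforward (FFL) loop products of a motif."""

    FL1: int
    FL2: int
    FL3: int
    FL12: int
    FL13: int
    FL23: int
    FL123: int
    FL213: int
    FFL32: int
    FFL31: int

    @property
    def feedback_products(self) -> tuple:
        return (
            self.FL1, self.FL2, self.FL3, self.FL12, self.FL13, self.FL23,
            self.FL123, self.FL213,
        )

    @property
    def feedforward_products(self) -> tuple:
        return (self.FFL32, self.FFL31)


def loop_products(A: np.ndarray) -> LoopProfile:
    """Autoregulatory, two-gene, three-gene feedback and feedforward products."""
    A = np.asarray(A)
    return LoopProfile(
        FL1=int(A[0, 0]),
        FL2=int(A[1, 1]),
        FL3=int(A[2, 2]),
        FL12=int(A[1, 0] * A[0, 1]),
        FL13=int(A[2, 0] * A[0, 2]),
        FL23=int(A[1, 2] * A[2, 1]),
        FL123=int(A[2, 1] * A[1, 0] * A[0, 2]),
        FL213=int(A[2, 0] * A[0, 1] * A[1, 2]),
        FFL32=int(A[2, 1] * A[2, 0] * A[0, 1]),
        FFL31=int(A[2, 0] * A[2, 1] * A[1, 0]),
    )


@dataclass(frozen=True)
class MotifClass:
    has_incoherent_ffl: bool
    has_positive_fb: bool

    @property
    def label(self) -> str:
        if self.has_incoherent_ffl and self.has_positive_fb:
            return "both"
        if self.has_incoherent_ffl:
            return "ffl_only"
        if self.has_positive_fb:
            return "fb_only"
        return "neither"


def classify(A: np.ndarray) -> MotifClass:
    """Class a motif by incoherent feedforward and positive feedback content."""
    prof = loop_products(A)
    return MotifClass(
        has_incoherent_ffl=any(v < 0 for v in prof.feedforward_products),
        has_positive_fb=any(v > 0 for v in prof.feedback_products),
    )


def is_weakly_connected(A: np.ndarray) -> bool:
    """Weak connectivity of the signed digraph on the three genes."""
    G = nx.DiGraph()
    G.add_nodes_from(range(3))
    for k in range(3):
        for l in range(3):
            if A[k, l] != 0:
                G.add_edge(l, k)
    return nx.is_weakly_connected(G)


def motif_table(matrices=None):
    """One row per motif: flattened A, all loop products, class label.

    Defaults to the 1881 study representatives.  Returns a pandas
    DataFrame mirroring the shape of a motif catalog spreadsheet.
    """
    import pandas as pd

    if matrices is None:
        matrices = reduce_symmetry(filter_downstream(enumerate_all()))
    records = []
    for i, A in enumerate(matrices):
        prof = loop_products(A)
        cls = classify(A)
        rec = {"motif_id": i}
        for k in range(3):
            for l in range(3):
                rec[f"A{k + 1}{l + 1}"] = int(A[k, l])
        for name in FL_NAMES + FFL_NAMES:
            rec[name] = getattr(prof, name)
        rec["has_incoherent_ffl"] = cls.has_incoherent_ffl
        rec["has_positive_fb"] = cls.has_positive_fb
        rec["motif_class"] = cls.label
        records.append(rec)
    return pd.DataFrame.from_records(records)
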