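import numpy as np
import pytest
import scipy.optimize

from gpmono.gpmap import catalog_map, partial_order_covers
from gpmono.isotone import cover_matrix


@pytest.fixture
def mouseweight():
    """Two-locus mouse body-weight GP map (values in grams)."""
    return catalog_map("mouseweight")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def slsqp_isotonic(values, n_loci):
    """Independent oracle: generic constrained quadratic solve of the
    isotonic projection (minimize ||x - g||^2 s.t. all cover edges)."""
    C = cover_matrix(partial_order_covers(n_loci))
    g = np.asarray(values, float)
    res = scipy.optimize.minimize(
        lambda x: 0.5 * np.sum((x - g) ** 2),
        g,
        jac=lambda x: x - g,
        constraints=[{"type": "ineq", "fun": lambda x: C @ x, "jac": lambda x: C}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success
    return res.x
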