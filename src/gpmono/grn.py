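"""Diploid sigmoid gene-regulatory-network ODE models and the Monte-Carlo
protocol that turns them into three-locus GP maps.

Three diploid genes X1, X2, X3 are wired by a signed 3x3 connectivity
matrix.  Each allele copy i of gene k follows

    dx_ki/dt = alpha_ki * R_ki(y1, y2, y3) - gamma_ki * x_ki,
    y_k = x_k1 + x_k2,

where R_ki multiplies a Hill dose-response term S(y, theta, p) =
y^p / (y^p + theta^p) per regulator (1 - S for repression; the product of
two regulators' terms realises a Boolean AND; an unregulated gene has
R = 1).  The phenotype of a genotype is the equilibrium total expression
y3 of the downstream gene; assembling it over all 27 three-locus genotypes
yields a GP map.

Genotype-to-parameter maps: without pleiotropy the two alleles of a locus
differ only in their maximal production rate alpha ~ U(100, 200) (Hill
thresholds theta ~ U(20, 40) and steepnesses p ~ U(1, 10) drawn once per
gene-regulator pair, shared by both alleles); with pleiotropy each allele
carries its own alpha, theta and p.  Decay rates are fixed at gamma = 10.
Replicates where any genotype fails to reach a stable equilibrium (e.g.
sustained oscillation), or whose 27-value map is essentially flat, are
discarded rather than analysed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.integrate
import scipy.optimize

from .gpmap import GPMap
from .isotone import decompose_monotone
from .monotonicity import degree_of_monotonicity
from .varcomp import variance_components

__all__ = [
    "SimConfig",
    "DiploidNetworkParams",
    "Discard",
    "SimResult",
    "hill",
    "regulation_function",
    "rhs",
    "steady_state",
    "sample_genotype_parameters",
    "simulate_gpmap",
    "monte_carlo_study",
]

GAMMA = 10.0
ALPHA_RANGE = (100.0, 200.0)
THETA_RANGE = (20.0, 40.0)
STEEPNESS_RANGE = (1.0, 10.0)


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo protocol settings.

    flat_abs / flat_rel: a usable GP map needs absolute range (max - min)
    and relative range (absolute range / mean) both above these thresholds.
    min_usable_per_1000: motif-inclusion threshold, scaled in proportion to
    n_reps when the study is run below 1000 replicates.
    """

    pleiotropy: bool = False
    n_reps: int = 1000
    seed: int = 0
    flat_abs: float = 0.01
    flat_rel: float = 0.01
    conv_tol: float = 1e-6
    window: float = 10.0
    t_max: float = 1000.0
    min_usable_per_1000: int = 100
    zero_tol: float | None = None  # None = monotonicity module default

    @property
    def min_usable(self) -> int:
        return max(1, round(self.min_usable_per_1000 * self.n_reps / 1000))


@dataclass(frozen=True)
class DiploidNetworkParams:
    """Allelic parameter table for one network.

    alpha[k, i]: maximal production rate of allele variant i of gene k.
    theta[l, k, i], p[l, k, i]: Hill threshold and steepness for regulator
    l acting on allele variant i of gene k (meaningful only where
    A[k, l] != 0).  gamma: common decay rate.
    """

    A: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray
    p: np.ndarray
    gamma: float = GAMMA

    def swap_alleles(self, locus: int) -> "DiploidNetworkParams":
        """Interchange the two allelic variants of one locus (0-based)."""
        alpha = self.alpha.copy()
        theta = self.theta.copy()
        p = self.p.copy()
        alpha[locus] = alpha[locus, ::-1]
        theta[:, locus] = theta[:, locus, ::-1]
        p[:, locus] = p[:, locus, ::-1]
        return replace(self, alpha=alpha, theta=theta, p=p)


def hill(y: float, theta: float, p: float, mode: str = "activator") -> float:
    """Sigmoid dose-response S(y, theta, p) = y^p / (y^p + theta^p).

    theta is the regulator level giving half-maximal production; p sets the
    steepness.  Repression returns 1 - S.
    """
    if y < 0 or theta <= 0 or p <= 0:
        raise ValueError("require y >= 0, theta > 0, p > 0")
    if y == 0.0:
        s = 0.0
    else:
        # log-ratio form avoids overflow for extreme y or steep p
        t_log = p * (math.log(theta) - math.log(y))
        s = 0.0 if t_log > 700.0 else 1.0 / (1.0 + math.exp(t_log))
    if mode == "activator":
        return s
    if mode == "repressor":
        return 1.0 - s
    raise ValueError(f"unknown mode {mode!r}")


def regulation_function(
    A: np.ndarray, gene: int, allele: int, y, params: DiploidNetworkParams
) -> float:
    """Production-rate multiplier R_ki in [0, 1] for one allele copy.

    No regulators: production always switched on (R = 1).  One regulator:
    its Hill term.  Two regulators: the product of both terms (AND gate).
    """
    regulators = np.nonzero(A[gene])[0]
    if len(regulators) > 2:
        raise ValueError("at most two regulators per gene")
    r = 1.0
    for l in regulators:
        mode = "activator" if A[gene, l] > 0 else "repressor"
        r *= hill(y[l], params.theta[l, gene, allele], params.p[l, gene, allele], mode)
    return r


def _genotype_variants(counts) -> list[tuple[int, int]]:
    """Allelic-variant indices of the two copies per gene for a genotype."""
    lookup = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return [lookup[c] for c in counts]


def _compiled_rhs(A: np.ndarray, params: DiploidNetworkParams, counts):
    """Closure computing the 6 time-derivatives for one genotype.

    State layout: (x_11, x_12, x_21, x_22, x_31, x_32), gene-major, where
    the second index is the physical copy; each copy expresses the allelic
    variant dictated by the genotype.
    """
    variants = _genotype_variants(counts)
    alpha = np.array(
        [params.alpha[k, v] for k in range(3) for v in variants[k]]
    )
    gamma = params.gamma
    reg_info = []  # per state variable: list of (regulator, theta, p, is_activator)
    for k in range(3):
        for v in variants[k]:
            terms = [
                (l, params.theta[l, k, v], params.p[l, k, v], A[k, l] > 0)
                for l in np.nonzero(A[k])[0]
            ]
            reg_info.append(terms)

    def f(t, x):
        y = (x[0] + x[1], x[2] + x[3], x[4] + x[5])
        dx = np.empty(6)
        for i in range(6):
            r = 1.0
            for l, theta, p, act in reg_info[i]:
                yl = y[l]
                if yl <= 0.0:
                    s = 0.0
                else:
                    t_log = p * (math.log(theta) - math.log(yl))
                    s = 0.0 if t_log > 700.0 else 1.0 / (1.0 + math.exp(t_log))
                r *= s if act else 1.0 - s
            dx[i] = alpha[i] * r - gamma * x[i]
        return dx

    return f


def rhs(state, A: np.ndarray, params: DiploidNetworkParams, counts=(1, 1, 1)):
    """Time-derivatives of the six allele concentrations for one genotype."""
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError("state must have 6 components")
    return _compiled_rhs(A, params, counts)(0.0, state)


def steady_state(
    A: np.ndarray,
    params: DiploidNetworkParams,
    config: SimConfig = SimConfig(),
    counts=(1, 1, 1),
):
    """Stable equilibrium of one genotype's ODE system, or None.

    Integrates from the all-zero state in windows until the state stops
    moving (max relative change per window and residual both below
    conv_tol), then polishes the equilibrium with a root solve so the
    reported phenotype carries no integration error.  Non-convergence by
    t_max — including sustained oscillation — and failed polishing both
    return None.
    """
    f = _compiled_rhs(A, params, counts)
    x = np.zeros(6)
    t = 0.0
    converged = False
    while t < config.t_max:
        sol = scipy.integrate.solve_ivp(
            f, (t, t + config.window), x, method="LSODA", rtol=1e-8, atol=1e-10
        )
        if not sol.success:
            return None
        x_new = sol.y[:, -1]
        scale = max(float(np.max(np.abs(x_new))), 1.0)
        moved = float(np.max(np.abs(x_new - x))) / scale
        resid = float(np.max(np.abs(f(0.0, x_new)))) / scale
        x = x_new
        t += config.window
        if moved < config.conv_tol and resid < config.conv_tol:
            converged = True
            break
    if not converged:
        return None
    root = scipy.optimize.root(lambda z: f(0.0, z), x, method="hybr")
    if not root.success:
        return None
    x_eq = root.x
    scale = max(float(np.max(np.abs(x_eq))), 1.0)
    if (
        float(np.max(np.abs(f(0.0, x_eq)))) > 1e-9 * scale
        or np.any(x_eq < -1e-9 * scale)
        or float(np.max(np.abs(x_eq - x))) > 1e-3 * scale
    ):
        return None
    x_eq = np.clip(x_eq, 0.0, None)
    y = np.array([x_eq[0] + x_eq[1], x_eq[2] + x_eq[3], x_eq[4] + x_eq[5]])
    return x_eq, y


def sample_genotype_parameters(
    A: np.ndarray, pleiotropy: bool, rng: np.random.Generator
) -> DiploidNetworkParams:
    """Draw one replicate's allelic parameter table.

    alpha ~ U(100, 200) per gene and allele.  theta ~ U(20, 40) and
    p ~ U(1, 10) per gene-regulator pair: per allele when the genotype-to-
    parameter map is pleiotropic, shared across alleles otherwise.
    """
    alpha = rng.uniform(*ALPHA_RANGE, size=(3, 2))
    if pleiotropy:
        theta = rng.uniform(*THETA_RANGE, size=(3, 3, 2))
        p = rng.uniform(*STEEPNESS_RANGE, size=(3, 3, 2))
    else:
        theta = np.repeat(rng.uniform(*THETA_RANGE, size=(3, 3, 1)), 2, axis=2)
        p = np.repeat(rng.uniform(*STEEPNESS_RANGE, size=(3, 3, 1)), 2, axis=2)
    return DiploidNetworkParams(A=np.asarray(A, dtype=int), alpha=alpha, theta=theta, p=p)


@dataclass(frozen=True)
class Discard:
    """Reason a replicate was excluded: 'non-convergence' or 'flat'."""

    reason: str


def simulate_gpmap(
    A: np.ndarray, params: DiploidNetworkParams, config: SimConfig = SimConfig()
):
    """GP map over the 27 three-locus genotypes, or a Discard.

    Heterozygotes express one copy of each allelic variant; homozygotes
    express two copies of the same variant.  The phenotype is equilibrium
    y3.  A replicate is discarded when any genotype fails to converge or
    when the map is essentially flat (absolute range <= flat_abs or
    relative range <= flat_rel).
    """
    values = np.empty(27)
    idx = 0
    for c1 in range(3):
        for c2 in range(3):
            for c3 in range(3):
                eq = steady_state(A, params, config, counts=(c1, c2, c3))
                if eq is None:
                    return Discard("non-convergence")
                values[idx] = eq[1][2]
                idx += 1
    abs_range = float(np.ptp(values))
    mean = float(np.mean(values))
    if abs_range <= config.flat_abs or mean <= 0 or abs_range / mean <= config.flat_rel:
        return Discard("flat")
    return GPMap(n_loci=3, values=values)


@dataclass
class SimResult:
    """Per-motif Monte-Carlo outcome."""

    motif_id: int
    A: np.ndarray
    n_reps: int
    usable: int = 0
    discarded_nonconv: int = 0
    discarded_flat: int = 0
    included: bool = False
    order_breaking_hist: np.ndarray = field(default_factory=lambda: np.zeros(4, int))
    m_values: list = field(default_factory=list)
    r2_values: list = field(default_factory=list)
    va_vg_values: list = field(default_factory=list)
    gpmaps: list = field(default_factory=list)


def _replicate_rng(seed: int, motif_id: int, rep: int) -> np.random.Generator:
    """Deterministic per-motif, per-replicate stream from one root seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(motif_id, rep))
    return np.random.default_rng(ss)


def monte_carlo_study(
    motifs, config: SimConfig, keep_maps: bool = False, measures: bool = True
) -> list[SimResult]:
    """Run the Monte-Carlo protocol over a list of connectivity matrices.

    For each motif, n_reps parameter tables are drawn and simulated; usable
    maps are scored (order-breaking locus count, degree of monotonicity m,
    R2_mono, V_A/V_G).  A motif is 'included' when its usable count reaches
    the min-usable threshold (100 per 1000 replicates, scaled).  All
    randomness derives from config.seed via per-(motif, replicate) streams,
    so any subset of the study reproduces exactly.
    """
    results = []
    for motif_id, A in enumerate(motifs):
        res = SimResult(motif_id=motif_id, A=np.asarray(A, int), n_reps=config.n_reps)
        for rep in range(config.n_reps):
            rng = _replicate_rng(config.seed, motif_id, rep)
            params = sample_genotype_parameters(A, config.pleiotropy, rng)
            outcome = simulate_gpmap(A, params, config)
            if isinstance(outcome, Discard):
                if outcome.reason == "flat":
                    res.discarded_flat += 1
                else:
                    res.discarded_nonconv += 1
                continue
            res.usable += 1
            if keep_maps:
                res.gpmaps.append(outcome)
            if measures:
                ztol = config.zero_tol
                m, report = degree_of_monotonicity(outcome, zero_tol=ztol)
                res.order_breaking_hist[report.order_breaking_count] += 1
                res.m_values.append(m)
                res.r2_values.append(decompose_monotone(outcome).r2_mono)
                res.va_vg_values.append(variance_components(outcome).ratio)
        res.included = res.usable >= config.min_usable
        results.append(res)
    return results
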