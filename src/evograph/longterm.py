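"""Long-term origin-fixation (weak-mutation) dynamics.

In the low-mutation-rate regime the population is monomorphic between
fixation events and its fitness performs a Markov jump process with rates
``mu * rho(f'|f) * Phi(f', f)``. This module provides the fixation-ratio
Psi, power-law (effective-population-size) exponent fitting, closed-form
House-of-Cards steady states and their moments, stationary distributions
of the discrete-fitness jump chain by direct global-balance solve, and
origin-fixation Monte Carlo.

The mutation probability mu cancels from every stationary quantity (it is
a common factor of all rates) and is kept for bookkeeping only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .fixation_exact import (
    average_fixation,
    fixation_complete_closed,
    fixation_star_average,
)
from .graph_core import Graph
from .update_rules import UpdateRule

PhiProvider = Callable[[float, float], float]

#: Default near-neutral window of fitness ratios used when fitting nu.
DEFAULT_NU_RATIOS = (0.8, 0.9, 1.1, 1.25)


# -- fixation-probability providers ---------------------------------------


def exact_phi_provider(g: Graph, rule: UpdateRule) -> PhiProvider:
    """Memoised Phi(f', f) from the full-configuration exact solver."""

    @lru_cache(maxsize=100_000)
    def phi(fprime: float, f: float) -> float:
        return average_fixation(g, rule, fprime, f)

    return phi


def complete_phi_provider(n: int, order: str = "dB") -> PhiProvider:
    """Closed-form complete-graph Phi(f', f)."""

    def phi(fprime: float, f: float) -> float:
        return fixation_complete_closed(n, fprime, f, order)

    return phi


def star_phi_provider(n: int, rule: UpdateRule) -> PhiProvider:
    """Memoised initialisation-averaged star Phi via the reduced chain."""

    @lru_cache(maxsize=100_000)
    def phi(fprime: float, f: float) -> float:
        return fixation_star_average(n, rule, fprime, f)

    return phi


# -- fixation ratio and effective population size --------------------------


def psi_ratio(phi: PhiProvider, fprime: float, f: float) -> float:
    """Fixation-probability ratio Psi = Phi(f', f) / Phi(f, f').

    Returns ``inf`` when the backward probability is zero but the forward
    one is not (e.g. large-N limits for deleterious back-mutations).
    """
    fwd = phi(fprime, f)
    bwd = phi(f, fprime)
    if bwd == 0.0:
        if fwd == 0.0:
            raise ValidationError("Psi undefined: both fixation probabilities are zero")
        return math.inf
    return fwd / bwd


@dataclass(frozen=True)
class NuFit:
    """Least-squares power-law exponent of Psi with a reversibility diagnostic."""

    nu: float
    max_residual: float
    ratios: tuple[float, ...]
    psis: tuple[float, ...]


def fit_nu(ratios: Sequence[float], psis: Sequence[float]) -> NuFit:
    """Fit Psi ~ (f'/f)^nu through the origin in log-log coordinates.

    ``max_residual`` is the largest |log Psi - nu*log ratio|; zero iff the
    origin-fixation chain is exactly reversible on the sampled ratios.
    """
    ratios = tuple(float(r) for r in ratios)
    psis = tuple(float(p) for p in psis)
    if len(ratios) != len(psis):
        raise ValidationError("ratios and psis must have equal length")
    if len(set(ratios)) < 2:
        raise ValidationError("need at least 2 distinct fitness ratios")
    if any(r <= 0 for r in ratios) or any(p <= 0 or not math.isfinite(p) for p in psis):
        raise ValidationError("ratios and Psi values must be finite and positive")
    x = np.log(ratios)
    y = np.log(psis)
    nu = float(x @ y / (x @ x))
    resid = float(np.abs(y - nu * x).max())
    return NuFit(nu, resid, ratios, psis)


def fit_nu_from_phi(
    phi: PhiProvider, ratios: Sequence[float] = DEFAULT_NU_RATIOS, f: float = 1.0
) -> NuFit:
    """Evaluate Psi on ``f' = ratio * f`` pairs and fit the exponent."""
    psis = [psi_ratio(phi, r * f, f) for r in ratios]
    return fit_nu(ratios, psis)


# -- steady states ---------------------------------------------------------


@dataclass(frozen=True)
class StationaryFitness:
    """A steady-state fitness distribution with its first two moments.

    Either continuous (``support`` an interval, density ~ f^nu * rho) or
    discrete (``grid``/``pmf`` set, solved from global balance).
    """

    mean: float
    std: float
    nu: float | None = None
    support: tuple[float, float] | None = None
    grid: tuple[float, ...] | None = None
    pmf: tuple[float, ...] | None = None
    moment: float | None = None
    balance_residual: float | None = None


def _uniform_power_moment(nu: float, fmin: float, fmax: float, k: int) -> float:
    """E[f^k] under density proportional to f^nu on [fmin, fmax]."""
    a, b = nu + 1.0, nu + 1.0 + k
    return (a / b) * (fmax**b - fmin**b) / (fmax**a - fmin**a)


def hoc_stationary(nu: float, fmin: float, fmax: float) -> StationaryFitness:
    """House-of-Cards steady state for a uniform mutant-fitness density.

    The stationary density is proportional to f^nu on [fmin, fmax]; the
    normalising constant is the nu-th moment of rho.
    """
    if nu < 0:
        raise ValidationError("nu must be >= 0")
    if not 0 < fmin < fmax:
        raise ValidationError("need 0 < fmin < fmax")
    mean = _uniform_power_moment(nu, fmin, fmax, 1)
    m2 = _uniform_power_moment(nu, fmin, fmax, 2)
    var = max(m2 - mean * mean, 0.0)
    moment = (fmax ** (nu + 1) - fmin ** (nu + 1)) / ((nu + 1) * (fmax - fmin))
    return StationaryFitness(
        mean=mean,
        std=math.sqrt(var),
        nu=nu,
        support=(fmin, fmax),
        moment=moment,
    )


def _discrete_transition_matrix(
    phi: PhiProvider, grid: Sequence[float]
) -> np.ndarray:
    """Row-stochastic jump chain on a fitness grid.

    Proposal: probability 1/2 to each nearest neighbour; at the
    boundaries the lost outward mass becomes a self-loop, preserving the
    symmetry of the proposal between neighbouring states. Acceptance is
    the fixation probability.
    """
    grid = list(grid)
    m = len(grid)
    if m >= 2 and any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("fitness grid must be strictly increasing")
    p = np.zeros((m, m))
    for i in range(m):
        for j in (i - 1, i + 1):
            if 0 <= j < m:
                acc = phi(grid[j], grid[i])
                if acc < 0:
                    raise ValidationError("fixation probabilities must be >= 0")
                p[i, j] = 0.5 * acc
        p[i, i] = 1.0 - p[i].sum() + p[i, i]
    return p


def discrete_chain_stationary(
    phi: PhiProvider, grid: Sequence[float], mu: float = 1e-3
) -> StationaryFitness:
    """Stationary distribution of the discrete-fitness origin-fixation chain.

    Solved as the left null vector of the global-balance system by direct
    linear solve — detailed balance is *not* assumed (it fails for most
    graphs). ``mu`` cancels and is accepted for interface symmetry only.
    """
    grid = tuple(float(x) for x in grid)
    if len(grid) == 1:
        return StationaryFitness(mean=grid[0], std=0.0, grid=grid, pmf=(1.0,))
    p = _discrete_transition_matrix(phi, grid)
    m = len(grid)
    off = p - np.diag(np.diag(p))
    if any((off[i, i + 1] == 0.0 or off[i + 1, i] == 0.0) for i in range(m - 1)):
        raise ValidationError("jump chain is reducible: a nearest-neighbour rate is zero")
    # pi (P - I) = 0 with sum(pi) = 1: replace one column by the constraint
    a = (p - np.eye(m)).T
    a[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = float(np.abs(pi @ p - pi).max())
    g = np.asarray(grid)
    mean = float(pi @ g)
    var = float(pi @ (g - mean) ** 2)
    return StationaryFitness(
        mean=mean,
        std=math.sqrt(max(var, 0.0)),
        grid=grid,
        pmf=tuple(pi.tolist()),
        balance_residual=resid,
    )


def detailed_balance_stationary(
    phi: PhiProvider, grid: Sequence[float]
) -> np.ndarray:
    """Product-of-ratios construction, valid only under detailed balance.

    Cross-check companion to :func:`discrete_chain_stationary`.
    """
    grid = tuple(float(x) for x in grid)
    w = [1.0]
    for a, b in zip(grid, grid[1:]):
        w.append(w[-1] * psi_ratio(phi, b, a))
    pi = np.asarray(w)
    return pi / pi.sum()


# -- origin-fixation Monte Carlo -------------------------------------------


@dataclass(frozen=True)
class MutationModel:
    """Mutant-fitness proposal for origin-fixation dynamics.

    ``kind='hoc-uniform'``: mutant fitness uniform on [fmin, fmax],
    independent of the parent (House of Cards). ``kind='discrete'``:
    nearest-neighbour proposal (probability 1/2 each) on ``grid``.
    ``mu`` is bookkeeping only (it sets the clock, not the steady state).
    """

    kind: str = "hoc-uniform"
    fmin: float = 1.0
    fmax: float = 10.0
    grid: tuple[float, ...] | None = None
    mu: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind == "hoc-uniform":
            if not 0 < self.fmin < self.fmax:
                raise ValidationError("need 0 < fmin < fmax")
        elif self.kind == "discrete":
            if not self.grid or len(self.grid) < 1:
                raise ValidationError("discrete model requires a fitness grid")
        else:
            raise ValidationError(f"unknown mutation model kind {self.kind!r}")


@dataclass(frozen=True)
class OriginFixationResult:
    """Time-averaged steady-state estimate from an origin-fixation run."""

    mean: float
    std: float
    standard_error: float
    n_steps: int
    burn_in: int
    n_accepted: int
    seed: int
    trajectory: np.ndarray


def origin_fixation_mc(
    phi: PhiProvider,
    model: MutationModel,
    n_steps: int,
    seed: int,
    burn_in: int = 0,
    f0: float | None = None,
    keep_trajectory: bool = True,
) -> OriginFixationResult:
    """Monte Carlo simulation of the origin-fixation chain.

    Each step proposes a mutant fitness from the model and accepts it with
    probability Phi(f', f). Rejected proposals are self-loops and *are*
    counted in the time average: mutations arrive at a fitness-independent
    rate, so proposal steps are the correct clock. The standard error of
    the mean uses 20 block means to absorb autocorrelation.
    """
    if n_steps <= burn_in:
        raise ValidationError("n_steps must exceed burn_in")
    rng = np.random.default_rng(seed)
    if model.kind == "hoc-uniform":
        f = float(f0) if f0 is not None else model.fmin + rng.random() * (
            model.fmax - model.fmin
        )
        samples = np.empty(n_steps)
        accepted = 0
        for t in range(n_steps):
            prop = model.fmin + rng.random() * (model.fmax - model.fmin)
            if rng.random() < phi(prop, f):
                f = prop
                accepted += 1
            samples[t] = f
    else:
        grid = model.grid
        m = len(grid)
        i = int(np.argmin(np.abs(np.asarray(grid) - f0))) if f0 is not None else int(
            rng.integers(m)
        )
        samples = np.empty(n_steps)
        accepted = 0
        for t in range(n_steps):
            j = i + (1 if rng.random() < 0.5 else -1)
            if 0 <= j < m and rng.random() < phi(grid[j], grid[i]):
                i = j
                accepted += 1
            samples[t] = grid[i]
    tail = samples[burn_in:]
    mean = float(tail.mean())
    std = float(tail.std())
    nblocks = min(20, len(tail))
    blocks = np.array_split(tail, nblocks)
    bm = np.array([b.mean() for b in blocks])
    se = float(bm.std(ddof=1) / math.sqrt(nblocks)) if nblocks > 1 else float("nan")
    return OriginFixationResult(
        mean=mean,
        std=std,
        standard_error=se,
        n_steps=n_steps,
        burn_in=burn_in,
        n_accepted=accepted,
        seed=seed,
        trajectory=samples if keep_trajectory else samples[:0],
    )
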