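"""Exact fixation probabilities.

Four routes are provided and cross-checked against each other in the test
suite:

* a full-configuration absorbing-chain solver over all 2^N mutant
  configurations (arbitrary small connected graphs, any rule),
* a reduced ("lumped") absorbing-chain solver for stars of any size,
  exploiting leaf exchangeability,
* closed forms for the complete graph and the star graph under dB,
* large-N limit formulas.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import CapacityError, ValidationError
from .graph_core import FULL_SOLVER_MAX_N, Graph
from .update_rules import UpdateRule, initialisation_distribution, kernel_mask

__all__ = [
    "fixation_per_node_exact",
    "average_fixation",
    "fixation_complete_closed",
    "fixation_star_closed",
    "fixation_star_reduced",
    "fixation_star_average",
    "limit_star_dB_temp",
    "limit_complete",
]


def _check_fitness(fprime: float, f: float) -> None:
    if fprime <= 0 or f <= 0:
        raise ValidationError("fitness values must be strictly positive")


# -- full-configuration solver --------------------------------------------


def fixation_per_node_exact(
    g: Graph, rule: UpdateRule, fprime: float, f: float
) -> np.ndarray:
    """Fixation probability from each singleton mutant start.

    Solves the linear system over all 2^N mutant configurations with the
    empty set (probability 0) and the full set (probability 1) absorbing.
    """
    _check_fitness(fprime, f)
    n = g.N
    if n > FULL_SOLVER_MAX_N:
        raise CapacityError(
            f"full-configuration solver supports N <= {FULL_SOLVER_MAX_N}, got {n}"
        )
    if not g.is_connected():
        raise ValidationError(
            "fixation probability is defined only if the graph is connected"
        )
    full = (1 << n) - 1
    n_trans = full - 1  # transient states are masks 1 .. full-1
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    b = np.zeros(n_trans)
    for mask in range(1, full):
        i = mask - 1
        diag = 1.0
        for succ, p in kernel_mask(g, rule.order, mask, fprime, f):
            if succ == mask:
                diag -= p
            elif succ == full:
                b[i] += p
            elif succ != 0:
                rows.append(i)
                cols.append(succ - 1)
                data.append(-p)
        rows.append(i)
        cols.append(i)
        data.append(diag)
    a = sp.csr_matrix((data, (rows, cols)), shape=(n_trans, n_trans))
    x = spla.spsolve(a.tocsc(), b)
    phi = np.array([x[(1 << i) - 1] for i in range(n)])
    return np.clip(phi, 0.0, 1.0)


def average_fixation(g: Graph, rule: UpdateRule, fprime: float, f: float) -> float:
    """Initialisation-averaged fixation probability Σ_i p_i φ_i."""
    phi = fixation_per_node_exact(g, rule, fprime, f)
    p = initialisation_distribution(g, rule).probabilities
    return float(p @ phi)


# -- closed forms ----------------------------------------------------------


def fixation_complete_closed(n: int, fprime: float, f: float, order: str = "dB") -> float:
    """Average fixation probability on the complete graph of size ``n``.

    dB: ((N-1)/N) * (1 - f/f') / (1 - (f/f')^(N-1)).
    Bd: the classical Moran formula (1 - f/f') / (1 - (f/f')^N).
    Both return 1/N at neutrality (continuous limit).
    """
    _check_fitness(fprime, f)
    if n < 2:
        raise ValidationError("complete graph needs N >= 2")
    x = f / fprime
    if order == "dB":
        pref, expo = (n - 1) / n, n - 1
    elif order == "Bd":
        pref, expo = 1.0, n
    else:
        raise ValidationError(f"unknown order {order!r}")
    if abs(x - 1.0) < 1e-12:
        return 1.0 / n
    logx = math.log(x)
    t = expo * logx
    if t > 500.0:  # x^expo overflows; Phi ~ pref*(x-1)*x^(-expo)
        return pref * math.exp(math.log(x - 1.0) - t)
    return pref * (1.0 - x) / (1.0 - math.exp(t))


def fixation_star_closed(n: int, start: str, fprime: float, f: float) -> float:
    """Closed-form dB fixation probability on the star of size ``n``.

    ``start`` is ``'centre'``, ``'leaf'`` or ``'temperature'`` (the
    temperature-initialised average ((N-1)·φ_centre + φ_leaf)/N).
    """
    _check_fitness(fprime, f)
    if n < 3:
        raise ValidationError("star requires N >= 3")
    r = fprime / f
    denom = 1.0 + (n - 2) / (1.0 + (n - 1) * r)
    if start == "centre":
        return (n - 1) / (n * denom)
    if start == "leaf":
        return r / ((n - 2 + 2 * r) * denom)
    if start == "temperature":
        centre = (n - 1) / (n * denom)
        leaf = r / ((n - 2 + 2 * r) * denom)
        return ((n - 1) * centre + leaf) / n
    raise ValidationError(f"start must be centre|leaf|temperature, got {start!r}")


# -- reduced star chain ----------------------------------------------------


def _star_reduced_solve(n: int, order: str, fprime: float, f: float) -> tuple[float, float]:
    """Fixation probabilities (from centre, from one leaf) on the star.

    Lumps the 2^N configurations into states (centre mutant?, number of
    mutant leaves) by leaf exchangeability; solves the 2N-state absorbing
    chain. Valid for N up to ~10^4.
    """
    _check_fitness(fprime, f)
    if n < 3:
        raise ValidationError("star requires N >= 3")
    leaves = n - 1

    def idx(c: int, k: int) -> int:
        return c * (leaves + 1) + k

    n_states = 2 * (leaves + 1)
    win, lose = idx(1, leaves), idx(0, 0)

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    rhs = np.zeros(n_states)

    def add(i: int, j: int, p: float) -> None:
        if p == 0.0:
            return
        if j == win:
            rhs[i] += p
        elif j != lose:
            rows.append(i)
            cols.append(j)
            data.append(-p)

    for c in (0, 1):
        for k in range(leaves + 1):
            i = idx(c, k)
            if i in (win, lose):
                continue
            trans: list[tuple[int, float]] = []
            if order == "dB":
                # death = centre (prob 1/N): birth among the leaves
                pk = k * fprime / (k * fprime + (leaves - k) * f)
                trans.append((idx(1, k), pk / n))
                trans.append((idx(0, k), (1.0 - pk) / n))
                # death = a leaf: it takes the centre's type
                if c == 1:
                    trans.append((idx(1, k + 1), (leaves - k) / n))  # wild leaf dies
                    trans.append((i, k / n))  # mutant leaf dies, no change
                else:
                    trans.append((idx(0, k - 1), k / n))  # mutant leaf dies
                    trans.append((i, (leaves - k) / n))
            else:  # Bd
                w = fprime * (c + k) + f * ((1 - c) + (leaves - k))
                fc = fprime if c else f
                # birth = centre, death uniform among leaves
                if c == 1:
                    trans.append((idx(1, k + 1), fc / w * (leaves - k) / leaves))
                    trans.append((i, fc / w * k / leaves))
                else:
                    trans.append((idx(0, k - 1), fc / w * k / leaves))
                    trans.append((i, fc / w * (leaves - k) / leaves))
                # birth = a leaf, death = centre (its only neighbour)
                trans.append((idx(1, k), k * fprime / w))
                trans.append((idx(0, k), (leaves - k) * f / w))
            diag = 1.0
            for j, p in trans:
                if j == i:
                    diag -= p
                else:
                    add(i, j, p)
            rows.append(i)
            cols.append(i)
            data.append(diag)

    # absorbing rows: identity (kept so indexing stays simple)
    for s in (win, lose):
        rows.append(s)
        cols.append(s)
        data.append(1.0)
    rhs[win] = 1.0

    a = sp.csr_matrix((data, (rows, cols)), shape=(n_states, n_states))
    if n_states <= 600:
        x = np.linalg.solve(a.toarray(), rhs)
    else:
        x = spla.spsolve(a.tocsc(), rhs)
    return float(x[idx(1, 0)]), float(x[idx(0, 1)])


def fixation_star_reduced(
    n: int, rule: UpdateRule, start: str, fprime: float, f: float
) -> float:
    """Reduced-chain star fixation probability from ``'centre'`` or ``'leaf'``."""
    centre, leaf = _star_reduced_solve(n, rule.order, fprime, f)
    if start == "centre":
        return centre
    if start == "leaf":
        return leaf
    raise ValidationError(f"start must be centre|leaf, got {start!r}")


def fixation_star_average(n: int, rule: UpdateRule, fprime: float, f: float) -> float:
    """Initialisation-averaged star fixation probability via the reduced chain.

    Temperature weighting puts (N-1)/N on the centre and 1/N total on the
    leaves; uniform puts 1/N on the centre. Mixed movement is the λ-convex
    combination of the two.
    """
    centre, leaf = _star_reduced_solve(n, rule.order, fprime, f)
    temp_avg = ((n - 1) * centre + leaf) / n
    unif_avg = (centre + (n - 1) * leaf) / n
    temp_is_parent = rule.order == "dB"  # dB^p temperature, Bd^p uniform
    if temp_is_parent:
        parent_val, offspring_val = temp_avg, unif_avg
    else:
        parent_val, offspring_val = unif_avg, temp_avg
    lam = rule.lam
    return lam * parent_val + (1.0 - lam) * offspring_val


# -- large-N limits --------------------------------------------------------


def limit_star_dB_temp(fprime: float, f: float) -> float:
    """N→∞ limit of the temperature-initialised dB star: f'/(f+f')."""
    _check_fitness(fprime, f)
    return fprime / (f + fprime)


def limit_complete(fprime: float, f: float) -> float:
    """N→∞ limit of the complete-graph fixation probability: max(0, 1-f/f')."""
    _check_fitness(fprime, f)
    return max(0.0, 1.0 - f / fprime)
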