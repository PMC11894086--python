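"""Monte Carlo estimation of fixation probabilities by forward simulation
of the Moran update kernels."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, ValidationError
from .graph_core import Graph
from .update_rules import UpdateRule, initialisation_distribution

#: Hard cap on Moran events per replicate (runaway guard).
MAX_EVENTS = 10**7


@dataclass(frozen=True)
class McEstimate:
    """A binomial fixation-probability estimate."""

    estimate: float
    n_reps: int
    standard_error: float
    seed: int
    n_fixed: int

    def within(self, exact: float, n_se: float = 4.0) -> bool:
        """True if ``exact`` lies within ``n_se`` standard errors."""
        se = max(self.standard_error, 1e-12)
        return abs(self.estimate - exact) <= n_se * se


def _run_one(
    nbrs: list[tuple[int, ...]],
    order: str,
    start: int,
    fprime: float,
    f: float,
    rng: np.random.Generator,
    max_events: int,
) -> bool:
    """Simulate one trajectory to absorption; True if the mutant fixes."""
    n = len(nbrs)
    mutant = [False] * n
    mutant[start] = True
    count = 1
    if order == "Bd":
        for _ in range(max_events):
            w = count * fprime + (n - count) * f
            x = rng.random() * w
            acc = 0.0
            b = n - 1
            for i in range(n):
                acc += fprime if mutant[i] else f
                if x < acc:
                    b = i
                    break
            nb = nbrs[b]
            d = nb[rng.integers(len(nb))]
            if mutant[d] != mutant[b]:
                mutant[d] = mutant[b]
                count += 1 if mutant[b] else -1
                if count == 0:
                    return False
                if count == n:
                    return True
        raise CapacityError(f"no absorption within {max_events} events")
    # dB
    for _ in range(max_events):
        d = int(rng.integers(n))
        nb = nbrs[d]
        w = 0.0
        for i in nb:
            w += fprime if mutant[i] else f
        x = rng.random() * w
        acc = 0.0
        b = nb[-1]
        for i in nb:
            acc += fprime if mutant[i] else f
            if x < acc:
                b = i
                break
        if mutant[d] != mutant[b]:
            mutant[d] = mutant[b]
            count += 1 if mutant[b] else -1
            if count == 0:
                return False
            if count == n:
                return True
    raise CapacityError(f"no absorption within {max_events} events")


def simulate_fixation(
    g: Graph,
    rule: UpdateRule,
    fprime: float,
    f: float,
    n_reps: int,
    seed: int,
    start: int | None = None,
    max_events: int = MAX_EVENTS,
) -> McEstimate:
    """Estimate the fixation probability from ``n_reps`` independent runs.

    Each replicate draws its start node from the rule's initialisation
    distribution unless ``start`` fixes it, then iterates the one-step
    kernel until absorption. Replicate ``i`` uses an independent stream
    derived from ``(seed, i)``, so results are reproducible and
    order-independent.
    """
    if fprime <= 0 or f <= 0:
        raise ValidationError("fitness values must be strictly positive")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if not g.is_connected():
        raise ValidationError(
            "fixation probability is defined only if the graph is connected"
        )
    if start is not None and not 0 <= start < g.N:
        raise ValidationError(f"start node {start} out of range")
    nbrs = g.neighbors
    init = None
    if start is None:
        p = initialisation_distribution(g, rule).probabilities
        init = np.cumsum(p)
    fixed = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        if start is None:
            s = int(np.searchsorted(init, rng.random(), side="right"))
            s = min(s, g.N - 1)
        else:
            s = start
        if _run_one(nbrs, rule.order, s, fprime, f, rng, max_events):
            fixed += 1
    est = fixed / n_reps
    se = math.sqrt(est * (1.0 - est) / n_reps)
    return McEstimate(est, n_reps, se, seed, fixed)
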