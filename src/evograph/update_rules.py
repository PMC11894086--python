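"""The four Moran update rules Bd^o, dB^o, Bd^p, dB^p (plus mixed
movement), their mutant-initialisation distributions, and the one-step
transition kernel on mutant configurations.

Naming: the capital letter of the order marks the event where selection
acts (Bd: fitness-proportional birth then uniform neighbour death; dB:
uniform death then fitness-proportional neighbour birth). The mover says
which daughter cell occupies the vacated node; without mutation the two
daughters are identical, so the mover changes only where the *initial*
mutant appears, never the mutation-free kernel.

Rule/initialisation correspondence:

====== =========== ==================
order  mover       initialisation
====== =========== ==================
Bd     offspring   temperature
Bd     parent      uniform
dB     offspring   uniform
dB     parent      temperature
====== =========== ==================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

import numpy as np

from .errors import ValidationError
from .graph_core import Graph, temperature

ORDERS = ("Bd", "dB")
MOVERS = ("offspring", "parent", "mixed")


@dataclass(frozen=True)
class UpdateRule:
    """Event order + mover choice, with optional mixed movement.

    ``parent_move_prob`` (λ) is only meaningful for ``mover='mixed'``:
    at each reproduction event the parent moves with probability λ
    (λ=0 is pure offspring moving, λ=1 pure parent moving).
    """

    order: str
    mover: str
    parent_move_prob: float | None = None

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValidationError(f"order must be one of {ORDERS}, got {self.order!r}")
        if self.mover not in MOVERS:
            raise ValidationError(f"mover must be one of {MOVERS}, got {self.mover!r}")
        if self.mover == "mixed":
            lam = self.parent_move_prob
            if lam is None or not 0.0 <= lam <= 1.0:
                raise ValidationError("mixed mover requires parent_move_prob in [0, 1]")
        elif self.parent_move_prob is not None:
            raise ValidationError("parent_move_prob is only valid with mover='mixed'")

    @property
    def lam(self) -> float:
        """Effective parent-move probability λ."""
        if self.mover == "parent":
            return 1.0
        if self.mover == "offspring":
            return 0.0
        return float(self.parent_move_prob)  # type: ignore[arg-type]

    def spelled(self) -> str:
        if self.mover == "mixed":
            return f"{self.order}-mix:{self.parent_move_prob:g}"
        return f"{self.order}-{self.mover[0]}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.spelled()


BD_O = UpdateRule("Bd", "offspring")
BD_P = UpdateRule("Bd", "parent")
DB_O = UpdateRule("dB", "offspring")
DB_P = UpdateRule("dB", "parent")


def parse_rule(spec: str) -> UpdateRule:
    """Parse a CLI rule spelling: Bd-o, Bd-p, dB-o, dB-p, Bd-mix:<λ>, dB-mix:<λ>."""
    spec = spec.strip()
    try:
        order, rest = spec.split("-", 1)
    except ValueError:
        raise ValidationError(f"cannot parse rule {spec!r}") from None
    if rest == "o":
        return UpdateRule(order, "offspring")
    if rest == "p":
        return UpdateRule(order, "parent")
    if rest.startswith("mix:"):
        try:
            lam = float(rest[4:])
        except ValueError:
            raise ValidationError(f"cannot parse λ in rule {spec!r}") from None
        return UpdateRule(order, "mixed", lam)
    raise ValidationError(f"cannot parse rule {spec!r}")


# -- initialisation --------------------------------------------------------


@dataclass(frozen=True)
class InitialisationDistribution:
    """Probability distribution of the initial mutant's node."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("initialisation probabilities must be >= 0 and sum to 1")
        p.setflags(write=False)
        object.__setattr__(self, "probabilities", p)


def _pure_init(g: Graph, order: str, mover: str) -> np.ndarray:
    temp_init = (order == "Bd" and mover == "offspring") or (
        order == "dB" and mover == "parent"
    )
    if temp_init:
        direction = "in" if order == "Bd" else "out"
        return temperature(g, direction).values / g.N
    return np.full(g.N, 1.0 / g.N)


def initialisation_distribution(g: Graph, rule: UpdateRule) -> InitialisationDistribution:
    """Where the first mutant appears under ``rule``.

    Bd^o and dB^p are temperature initialised; Bd^p and dB^o are uniform.
    Mixed movement gives the λ-convex combination of the two pure schemes.
    """
    if rule.mover == "mixed":
        lam = rule.lam
        p = lam * _pure_init(g, rule.order, "parent") + (1.0 - lam) * _pure_init(
            g, rule.order, "offspring"
        )
    else:
        p = _pure_init(g, rule.order, rule.mover)
    return InitialisationDistribution(p)


# -- transition kernel -----------------------------------------------------

MutantConfig = FrozenSet[int]


def kernel_mask(
    g: Graph, order: str, mask: int, fprime: float, f: float
) -> list[tuple[int, float]]:
    """One-step transition distribution from configuration ``mask``.

    ``mask`` is a bitmask of mutant-occupied nodes. Returns
    ``(successor_mask, probability)`` pairs (successor masks are unique);
    probabilities sum to 1. Mutation-free dynamics: the mover choice does
    not enter (both daughters share the parent's type).
    """
    if fprime <= 0 or f <= 0:
        raise ValidationError("fitness values must be strictly positive")
    n = g.N
    full = (1 << n) - 1
    if mask == 0 or mask == full:
        raise ValidationError("state is absorbing; kernel undefined")
    nbrs = g.neighbors
    fit = [fprime if (mask >> i) & 1 else f for i in range(n)]
    out: dict[int, float] = {}
    if order == "Bd":
        w_total = sum(fit)
        for b in range(n):
            pb = fit[b] / w_total
            nb = nbrs[b]
            share = pb / len(nb)
            tb = (mask >> b) & 1
            for d in nb:
                succ = (mask | (1 << d)) if tb else (mask & ~(1 << d))
                out[succ] = out.get(succ, 0.0) + share
    elif order == "dB":
        pd = 1.0 / n
        for d in range(n):
            nb = nbrs[d]
            w = sum(fit[b] for b in nb)
            for b in nb:
                tb = (mask >> b) & 1
                succ = (mask | (1 << d)) if tb else (mask & ~(1 << d))
                out[succ] = out.get(succ, 0.0) + pd * fit[b] / w
    else:
        raise ValidationError(f"unknown order {order!r}")
    return list(out.items())


def step_kernel(
    g: Graph,
    rule: UpdateRule,
    state: MutantConfig,
    fprime: float,
    f: float,
) -> dict[MutantConfig, float]:
    """Distribution over successor mutant configurations after one event."""
    mask = 0
    for i in state:
        if not 0 <= i < g.N:
            raise ValidationError(f"node {i} out of range for N={g.N}")
        mask |= 1 << i
    pairs = kernel_mask(g, rule.order, mask, fprime, f)
    return {
        frozenset(i for i in range(g.N) if (m >> i) & 1): p for m, p in pairs
    }
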