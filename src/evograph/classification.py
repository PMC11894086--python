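"""Fixation-probability profiles over a fitness grid and graph
classification relative to the complete graph of the same size.

Categories: AoS / SoS (amplifier / suppressor of selection: the sign of
the difference to the complete graph flips at neutrality), AoF / SoF
(amplifier / suppressor of fixation: one sign at every grid point),
piecewise-AoF (above up to a crossing fitness f* >= 1, below beyond it),
isothermal (regular graph), other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ValidationError
from .fixation_exact import average_fixation
from .graph_core import Graph, make_named_graph, sample_er_connected_many
from .update_rules import UpdateRule, initialisation_distribution

#: Mutant fitness grid used for classification (wild-type f = 1).
DEFAULT_GRID = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5)

CATEGORIES = ("AoS", "SoS", "AoF", "piecewise-AoF", "SoF", "isothermal", "other")

#: Noise floor of the exact solver; |Phi_G - Phi_C| below this is a tie.
DEFAULT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class FixationProfile:
    """Initialisation-averaged fixation probabilities over a fitness grid."""

    grid: tuple[float, ...]
    phi_avg: tuple[float, ...]
    per_node: tuple[tuple[float, ...], ...] | None = None

    def as_records(self) -> list[dict]:
        return [
            {"fprime": fp, "phi_avg": phi}
            for fp, phi in zip(self.grid, self.phi_avg)
        ]


@dataclass(frozen=True)
class ClassificationResult:
    """Category label plus the per-fitness comparison record.

    ``comparisons`` holds ``(f', sign(Phi_G - Phi_C))`` with sign in
    {-1, 0, +1} (0 = within tolerance). ``f_star`` is the crossing fitness
    for piecewise-AoF, at grid resolution. ``caveat`` flags the isothermal
    label, whose fixation-probability identity with the complete graph
    holds only for Bd updating.
    """

    category: str
    comparisons: tuple[tuple[float, int], ...]
    f_star: float | None = None
    caveat: str | None = None


def fixation_profile(
    g: Graph, rule: UpdateRule, grid: tuple[float, ...] = DEFAULT_GRID, f: float = 1.0
) -> FixationProfile:
    """Average fixation probability at each mutant fitness on ``grid``."""
    if not g.is_connected():
        raise ValidationError("classification requires a connected graph")
    phis = tuple(average_fixation(g, rule, fp, f) for fp in grid)
    return FixationProfile(tuple(grid), phis)


@lru_cache(maxsize=64)
def reference_profile(
    n: int, order: str, grid: tuple[float, ...] = DEFAULT_GRID, f: float = 1.0
) -> tuple[float, ...]:
    """Complete-graph reference Phi_C at size ``n`` for the given order.

    Computed with the exact solver (not a printed formula) so graph and
    reference go through the same numerical path.
    """
    complete = make_named_graph("complete", n)
    rule = UpdateRule(order, "offspring")
    return tuple(average_fixation(complete, rule, fp, f) for fp in grid)


def _signs(
    profile: FixationProfile, reference: tuple[float, ...], tolerance: float
) -> tuple[tuple[float, int], ...]:
    out = []
    for fp, phi, ref in zip(profile.grid, profile.phi_avg, reference):
        d = phi - ref
        out.append((fp, 0 if abs(d) <= tolerance else (1 if d > 0 else -1)))
    return tuple(out)


def classify_profile(
    g: Graph,
    profile: FixationProfile,
    reference: tuple[float, ...],
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClassificationResult:
    """Assign a category given a precomputed profile and reference."""
    comparisons = _signs(profile, reference, tolerance)
    if g.is_regular():
        return ClassificationResult(
            "isothermal",
            comparisons,
            caveat="identity with the complete graph holds only for Bd updating",
        )
    deleterious = [s for fp, s in comparisons if fp < 1.0]
    beneficial = [s for fp, s in comparisons if fp > 1.0]
    all_signs = [s for _, s in comparisons]
    if all(s > 0 for s in all_signs):
        return ClassificationResult("AoF", comparisons)
    if all(s < 0 for s in all_signs):
        return ClassificationResult("SoF", comparisons)
    # piecewise-AoF: above up to f*, below beyond, with f* >= 1
    above = [fp for fp, s in comparisons if s > 0]
    if above:
        f_star = max(above)
        if f_star >= 1.0 and all(
            (s > 0 if fp <= f_star else s < 0) for fp, s in comparisons
        ):
            return ClassificationResult("piecewise-AoF", comparisons, f_star=f_star)
    if deleterious and beneficial:
        if all(s < 0 for s in deleterious) and all(s > 0 for s in beneficial):
            return ClassificationResult("AoS", comparisons)
        if all(s > 0 for s in deleterious) and all(s < 0 for s in beneficial):
            return ClassificationResult("SoS", comparisons)
    return ClassificationResult("other", comparisons)


def classify(
    g: Graph,
    rule: UpdateRule,
    grid: tuple[float, ...] = DEFAULT_GRID,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ClassificationResult:
    """Classify ``g`` against the complete graph of the same size."""
    profile = fixation_profile(g, rule, grid)
    reference = reference_profile(g.N, rule.order, tuple(grid))
    return classify_profile(g, profile, reference, tolerance)


@dataclass
class CensusResult:
    """Category counts over a sample of connected ER graphs."""

    n: int
    p: float
    n_samples: int
    rule: str
    seed: int
    counts: dict[str, int]
    records: list[dict] = field(default_factory=list)


def census(
    n: int,
    p: float,
    n_samples: int,
    rule: UpdateRule,
    seed: int,
    grid: tuple[float, ...] = DEFAULT_GRID,
    tolerance: float = DEFAULT_TOLERANCE,
) -> CensusResult:
    """Classify ``n_samples`` connected ER(n, p) graphs.

    Isomorphic duplicates are not deduplicated; each record carries the
    graph's edge list as a fingerprint.
    """
    graphs = sample_er_connected_many(n, p, n_samples, seed)
    reference = reference_profile(n, rule.order, tuple(grid))
    counts = {c: 0 for c in CATEGORIES}
    records = []
    for i, g in enumerate(graphs):
        profile = fixation_profile(g, rule, grid)
        res = classify_profile(g, profile, reference, tolerance)
        counts[res.category] += 1
        records.append(
            {
                "index": i,
                "edges": g.edges(),
                "category": res.category,
                "f_star": res.f_star,
                "phi_avg": list(profile.phi_avg),
            }
        )
    return CensusResult(n, p, n_samples, rule.spelled(), seed, counts, records)
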