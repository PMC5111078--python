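"""Descriptive admixture statistics.

The genetic distance *d* between an individual and a population is the
minimum Euclidean distance between the individual's admixture vector and the
vectors of the population's members; medians of *d* summarise within- and
between-population diversity (the within-population form excludes the focal
individual, whose self-distance would be identically zero). Distances live on
the 0..sqrt(2) scale and are conventionally quoted as percentages
(0.027 -> "2.7%").

Also here: the nearest-population share table, the pairwise distance graph
(edges strictly below a threshold, default 0.3), component-wise two-sample
Kolmogorov-Smirnov comparisons (asymptotic p), and the conversion of admixture
dates from generations to calendar years (generation time 25 years).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import InputError
from .gps import ReferencePopulation, admixture_distance

__all__ = [
    "min_distance_to_population",
    "population_median_d",
    "nearest_population_shares",
    "build_distance_graph",
    "component_ks_test",
    "AdmixtureDate",
    "DateInterval",
    "generations_to_interval",
]


def min_distance_to_population(q, pop: ReferencePopulation, exclude_id: str | None = None) -> float:
    """Minimum admixture distance from q to the members of `pop`."""
    idx = [
        i for i, mid in enumerate(pop.member_ids) if exclude_id is None or mid != exclude_id
    ]
    if not idx:
        raise InputError(f"population {pop.label!r} empty after excluding {exclude_id!r}")
    q = np.asarray(q, dtype=float).ravel()
    return float(min(admixture_distance(q, pop.members[i]) for i in idx))


def population_median_d(
    members_a: np.ndarray,
    pop_b: ReferencePopulation,
    member_ids_a: Sequence[str] | None = None,
    *,
    within: bool = False,
) -> float:
    """Median over A's members of the minimum distance to population B.

    With ``within=True`` (or when A's ids coincide with B's), each member is
    excluded from B before taking its minimum — the within-population
    diversity statistic.
    """
    members_a = np.atleast_2d(np.asarray(members_a, dtype=float))
    if members_a.shape[0] == 0:
        raise InputError("population A has no members")
    ids = list(member_ids_a) if member_ids_a is not None else [None] * members_a.shape[0]
    ds = [
        min_distance_to_population(q, pop_b, exclude_id=ids[i] if within else None)
        for i, q in enumerate(members_a)
    ]
    return float(np.median(ds))


def nearest_population_shares(
    test_individuals: Sequence[tuple[str, np.ndarray]],
    populations: Sequence[ReferencePopulation],
) -> tuple[dict[str, float], set[str]]:
    """Share of test individuals whose nearest population (by min-distance) is each candidate.

    Returns ``(shares, tied_individuals)``; ties go to the lexicographically
    first population label and the individual is flagged. Shares sum to 1.
    """
    populations = list(populations)
    if not populations:
        raise InputError("need at least one candidate population")
    counts = {p.label: 0 for p in populations}
    tied: set[str] = set()
    for ind_id, q in test_individuals:
        ds = sorted(
            (min_distance_to_population(q, p, exclude_id=ind_id), p.label) for p in populations
        )
        if len(ds) > 1 and abs(ds[0][0] - ds[1][0]) < 1e-15:
            tied.add(ind_id)
        counts[ds[0][1]] += 1
    n = len(list(test_individuals))
    if n == 0:
        raise InputError("no test individuals")
    return {k: v / n for k, v in counts.items()}, tied


def build_distance_graph(
    individuals: Sequence[tuple[str, str, np.ndarray]],
    threshold: float = 0.3,
) -> nx.Graph:
    """Undirected graph with an edge wherever pairwise admixture distance < threshold.

    `individuals` are (id, population label, admixture vector) triples; node
    attribute ``label`` carries the population, edge attribute ``distance``
    the admixture distance.
    """
    individuals = list(individuals)
    if len(individuals) < 2:
        raise InputError("distance graph needs at least two individuals")
    g = nx.Graph(threshold=float(threshold))
    for ind_id, label, q in individuals:
        g.add_node(ind_id, label=label)
    for i in range(len(individuals)):
        for j in range(i + 1, len(individuals)):
            d = admixture_distance(individuals[i][2], individuals[j][2])
            if d < threshold:
                g.add_edge(individuals[i][0], individuals[j][0], distance=d)
    return g


def component_ks_test(vals_a, vals_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    Used to compare the distribution of one admixture component between two
    populations. Returns (D, p).
    """
    a = np.asarray(vals_a, dtype=float).ravel()
    b = np.asarray(vals_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InputError("KS test requires two non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class AdmixtureDate:
    """An admixture date in generations before a reference year."""

    generations: float
    se_generations: float = 0.0
    generation_time_years: float = 25.0
    reference_year: float = 1950.0

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise InputError("generations must be > 0")
        if self.se_generations < 0:
            raise InputError("se_generations must be >= 0")


@dataclass
class DateInterval:
    years_before_reference: float  # midpoint
    half_width_years: float
    calendar_interval: tuple[float, float]  # (earliest, latest) calendar year


def generations_to_interval(date: AdmixtureDate) -> DateInterval:
    """Convert generations +/- se into calendar years before the reference year."""
    mid = date.generations * date.generation_time_years
    half = date.se_generations * date.generation_time_years
    lo = date.reference_year - (mid + half)
    hi = date.reference_year - (mid - half)
    return DateInterval(mid, half, (lo, hi))
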