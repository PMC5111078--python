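"""End-to-end validation experiments on synthetic worlds.

These routines measure, from scratch, the behavioural contracts the package
is built around: the exact-match fixed point of coordinate prediction, the
mixed-origin midpoint contract on symmetric panels, parameter recovery of the
supervised admixture estimator, leave-one-out assignment error and accuracy,
convergence of the curation loop, agreement of Fisher's exact p-values with
exhaustive hypergeometric enumeration, and the type-I error rate of the
two-sample KS test. They are used by the test suite and by the reproduction
script; each takes explicit seeds and problem sizes so results are exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .admixture import SupervisedAdmixture
from .curation import CurationConfig, _loo_all, curate_panel
from .gps import (
    ReferencePopulation,
    admixture_distance,
    assignment_accuracy,
    gps_predict,
    great_circle_km,
)
from .gps import EARTH_RADIUS_KM, _move_toward
from .haplogroups import fisher_exact_2x2
from .stats import component_ks_test
from .world import SyntheticWorld, WorldConfig, make_world

__all__ = [
    "centroid_fixed_point_max_error_km",
    "symmetric_midpoint_trial",
    "midpoint_relative_errors",
    "EndToEndSummary",
    "end_to_end_summary",
    "fisher_enumeration_max_abs_diff",
    "ks_type_i_error_rate",
]


def centroid_fixed_point_max_error_km(panel) -> float:
    """Largest prediction error (km) over all reference centroids of a panel."""
    return max(
        great_circle_km(gps_predict(pop.centroid, panel).coordinate, pop.location)
        for pop in panel
    )


def symmetric_midpoint_trial(seed: int, n_far_pairs: int = 4) -> float:
    """One mixed-origin trial; returns |prediction - midpoint| / |AB|.

    Builds a symmetric panel: two parental populations A and B whose
    admixture vectors differ by a swap of two components, flanked by
    `n_far_pairs` pairs of far populations that are mirror images of each
    other in both admixture space (the same component swap) and geography
    (placed symmetrically about the AB axis, at distances consistent with
    the panel's km-per-genetic-unit scale). The 50/50 mixture of A and B is
    then predicted and compared with the geographic midpoint of A and B.
    """
    rng = np.random.default_rng(seed)
    K = 6
    a = rng.uniform(0.3, 0.45)
    rest = rng.dirichlet(np.ones(K - 2)) * (1 - (a + 0.1))
    qa = np.concatenate(([a, 0.1], rest))
    qa /= qa.sum()
    qb = qa.copy()
    qb[0], qb[1] = qa[1], qa[0]

    lat = rng.uniform(15, 45)
    lon = rng.uniform(30, 70)
    half_deg = rng.uniform(4, 10)
    A = (lat, lon - half_deg)
    B = (lat, lon + half_deg)
    ab_km = great_circle_km(A, B)
    rho = ab_km / admixture_distance(qa, qb)  # km per unit genetic distance

    panel = [
        ReferencePopulation("A", A, qa[None, :]),
        ReferencePopulation("B", B, qb[None, :]),
    ]
    q = 0.5 * (qa + qb)
    for i in range(n_far_pairs):
        qf = rng.dirichlet(np.ones(K)) * 0.35
        qf[2 + (i % (K - 2))] += 0.65
        qf /= qf.sum()
        qfs = qf.copy()
        qfs[0], qfs[1] = qf[1], qf[0]
        d_gen = admixture_distance(q, qf)
        dlat = math.degrees(rho * d_gen / EARTH_RADIUS_KM) * rng.uniform(0.6, 1.0)
        sign = 1 if i % 2 == 0 else -1
        lat_f = float(np.clip(lat + sign * dlat, -89, 89))
        panel.append(ReferencePopulation(f"F{i}a", (lat_f, lon - half_deg * 0.5), qf[None, :]))
        panel.append(ReferencePopulation(f"F{i}b", (lat_f, lon + half_deg * 0.5), qfs[None, :]))

    pred = gps_predict(q, panel).coordinate
    midpoint = _move_toward(A, B, ab_km / 2)
    return great_circle_km(pred, midpoint) / ab_km


def midpoint_relative_errors(seeds) -> list[float]:
    """Mixed-origin relative errors over a collection of trial seeds."""
    return [symmetric_midpoint_trial(int(s)) for s in seeds]


@dataclass
class EndToEndSummary:
    """Metrics of the full synthetic pipeline on one world."""

    admixture_rmse: float
    loo_median_error_km: float
    accuracy_250km: float
    accuracy_500km: float
    curation_rounds: int
    curation_converged: bool
    curation_final_accuracy: float
    n_individuals: int
    n_loci: int


def end_to_end_summary(
    seed: int = 1,
    config: WorldConfig | None = None,
    *,
    em_tol: float = 1e-7,
    em_max_iter: int = 2000,
    curation_max_rounds: int = 10,
) -> EndToEndSummary:
    """Generate a world, re-estimate admixture from genotypes, run leave-one-out
    prediction, score assignment accuracy, and run the curation loop."""
    config = config or WorldConfig(seed=seed)
    world = make_world(config)

    est = SupervisedAdmixture(tol=em_tol, max_iter=em_max_iter).fit(world.ancestral_freqs)
    Q = est.transform(world.genotypes)
    rmse = float(np.sqrt(np.mean((Q - world.admixture) ** 2)))

    loo = _loo_all(world.panel, 10)
    site = {p.name: p.location for p in world.panel}
    errors = np.array(
        [
            great_circle_km(r.coordinate, site[name])
            for name, results in loo.items()
            for r in results
        ]
    )
    predictions = [r for results in loo.values() for r in results]
    acc = assignment_accuracy(
        predictions, world.truth_regions(), world.oracle(), [250.0, 500.0]
    )

    _, report = curate_panel(
        world.panel,
        CurationConfig(max_rounds=curation_max_rounds),
        oracle=world.oracle(),
        seed=seed,
        regions=world.region_of,
    )
    return EndToEndSummary(
        admixture_rmse=rmse,
        loo_median_error_km=float(np.median(errors)),
        accuracy_250km=acc[250.0],
        accuracy_500km=acc[500.0],
        curation_rounds=report.n_rounds,
        curation_converged=report.converged,
        curation_final_accuracy=report.accuracy_trace[-1],
        n_individuals=world.n_individuals,
        n_loci=config.n_loci,
    )


def _fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)

    def point(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-7))


def fisher_enumeration_max_abs_diff(seed: int, n_tables: int = 100, max_count: int = 30) -> float:
    """Largest |p_implementation - p_enumeration| over random 2x2 tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    while checked < n_tables:
        a, b, c, d = (int(x) for x in rng.integers(0, max_count, size=4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        p, _ = fisher_exact_2x2(a, b, c, d)
        worst = max(worst, abs(p - _fisher_two_sided_enumeration(a, b, c, d)))
        checked += 1
    return worst


def ks_type_i_error_rate(
    seed: int, n_replicates: int = 1000, n_per_sample: int = 100, alpha: float = 0.05
) -> float:
    """Rejection rate of the KS test on same-distribution uniform samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.uniform(size=n_per_sample)
        b = rng.uniform(size=n_per_sample)
        _, p = component_ks_test(a, b)
        rejections += p < alpha
    return rejections / n_replicates
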