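"""Iterative reference-panel curation.

A reference panel is only useful for biogeographic prediction if every
population in it is genetically homogeneous and geographically faithful. The
curation loop enforces this with three ingredients:

* **subpopulation splitting** — k-means (k = 2, best of five replications) on
  a population's member admixture vectors; the split is accepted when the
  explained-variance ratio (between-cluster SS / total SS) passes the
  acceptance criterion and surviving clusters keep more than three members
  (smaller clusters are removed, populations under four members are left
  untouched);
* **population-level leave-one-out** — each individual is predicted with the
  whole of its parent population (all subpopulations) removed from the panel,
  a stricter check than per-individual exclusion;
* **retention** — individuals predicted inside their region or strictly less
  than `retain_km` (default 200 km) outside it are kept; the panel is
  recompiled from the survivors, re-split, and the loop repeats until the
  correct-assignment rate exceeds `target_accuracy` (default 80%) or
  `max_rounds` is hit.

The printed acceptance-ratio rule this mirrors is ambiguous in its source
material, so the direction of the inequality is configurable
(``ratio_mode``): ``accept_above`` (default) accepts splits whose clusters
explain at least ``accept_ratio`` of the total variance; ``accept_below``
takes the literal reading (< 0.9) instead. The mode used is echoed in the
curation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import ConfigurationError, InputError
from .gps import GeographicPositioning, PredictionResult, ReferencePopulation

__all__ = [
    "CurationConfig",
    "CurationReport",
    "split_population",
    "loo_population_predict",
    "curate_panel",
    "PanelCurator",
]


@dataclass
class CurationConfig:
    """Tunable parameters of the curation loop (see module docstring)."""

    k_candidates: tuple[int, ...] = (2,)
    kmeans_replications: int = 5
    accept_ratio: float = 0.9
    ratio_mode: str = "accept_above"  # or "accept_below" (literal reading)
    min_cluster_size: int = 4  # clusters with fewer members are removed
    retain_km: float = 200.0
    target_accuracy: float = 0.8
    max_rounds: int = 10
    n_neighbors: int = 10  # M used by the leave-one-out predictor

    def validate(self) -> None:
        if not (0.0 < self.accept_ratio <= 1.0):
            raise ConfigurationError("accept_ratio: must be in (0, 1]")
        if self.retain_km < 0:
            raise ConfigurationError("retain_km: must be >= 0")
        if not (0.0 < self.target_accuracy <= 1.0):
            raise ConfigurationError("target_accuracy: must be in (0, 1]")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds: must be >= 1")
        if self.ratio_mode not in ("accept_above", "accept_below"):
            raise ConfigurationError("ratio_mode: must be 'accept_above' or 'accept_below'")
        if any(k < 2 for k in self.k_candidates):
            raise ConfigurationError("k_candidates: k must be >= 2")


@dataclass
class CurationReport:
    """Per-round trace of the curation loop."""

    accuracy_trace: list[float] = field(default_factory=list)
    removed_per_round: list[int] = field(default_factory=list)
    populations_per_round: list[int] = field(default_factory=list)
    converged: bool = False
    n_rounds: int = 0
    ratio_mode: str = "accept_above"

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# splitting


def _explained_variance_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster sum of squares over total sum of squares."""
    grand = X.mean(axis=0)
    tss = float(((X - grand) ** 2).sum())
    if tss <= 0:
        return 0.0
    bss = 0.0
    for lbl in np.unique(labels):
        sub = X[labels == lbl]
        bss += sub.shape[0] * float(((sub.mean(axis=0) - grand) ** 2).sum())
    return bss / tss


def split_population(
    members: np.ndarray,
    config: CurationConfig | None = None,
    seed: int | None = 0,
) -> list[np.ndarray]:
    """Cluster a population's members into subpopulations.

    Returns a list of member-index arrays (one per accepted cluster, in
    cluster-label order). Populations with fewer than four members, members
    that are all identical, or splits failing the acceptance-ratio or
    cluster-size rules come back as a single cluster of all indexes. When the
    ratio criterion holds but one cluster is too small, the small cluster's
    members are dropped (not returned in any cluster).
    """
    config = config or CurationConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(members, dtype=float))
    n = X.shape[0]
    all_idx = [np.arange(n)]
    if n < 4:
        return all_idx
    if np.allclose(X, X[0]):
        return all_idx

    best: tuple[float, np.ndarray] | None = None
    for k in config.k_candidates:
        if n < k:
            continue
        km = KMeans(
            n_clusters=k,
            n_init=config.kmeans_replications,
            random_state=seed if seed is not None else 0,
        ).fit(X)
        ratio = _explained_variance_ratio(X, km.labels_)
        if best is None or ratio > best[0]:
            best = (ratio, km.labels_)
    if best is None:
        return all_idx
    ratio, labels = best
    accept = ratio >= config.accept_ratio if config.ratio_mode == "accept_above" else ratio < config.accept_ratio
    if not accept:
        return all_idx
    clusters = [np.flatnonzero(labels == lbl) for lbl in np.unique(labels)]
    surviving = [c for c in clusters if c.size >= config.min_cluster_size]
    if not surviving:
        return all_idx
    return surviving


def _resplit(panel: Sequence[ReferencePopulation], config: CurationConfig, seed: int) -> list[ReferencePopulation]:
    out: list[ReferencePopulation] = []
    for j, pop in enumerate(panel):
        clusters = split_population(pop.members, config, seed=seed + j)
        if len(clusters) == 1 and clusters[0].size == pop.n_members:
            out.append(pop)
            continue
        for c, idx in enumerate(clusters, start=1):
            sub = str(c) if len(clusters) > 1 else pop.subpopulation
            out.append(
                ReferencePopulation(
                    name=pop.name,
                    location=pop.location,
                    members=pop.members[idx],
                    member_ids=[pop.member_ids[i] for i in idx],
                    subpopulation=sub,
                )
            )
    return out


# ---------------------------------------------------------------------------
# leave-one-out prediction


def loo_population_predict(
    panel: Sequence[ReferencePopulation], target: str, M: int = 10, *, weight_power: float = 4.0
) -> list[PredictionResult]:
    """Predict every member of `target` with the whole population held out.

    `target` is a parent population name; all its subpopulations are excluded
    from the panel together.
    """
    panel = list(panel)
    held = [p for p in panel if p.name == target]
    if not held:
        raise InputError(f"target population {target!r} not in panel")
    rest = [p for p in panel if p.name != target]
    if not rest:
        raise InputError(f"removing {target!r} leaves an empty panel")
    engine = GeographicPositioning(n_neighbors=M, weight_power=weight_power).fit_panel(rest)
    results: list[PredictionResult] = []
    for pop in held:
        results.extend(engine.predict_result(pop.members, ids=pop.member_ids))
    return results


def _loo_all(
    panel: Sequence[ReferencePopulation], M: int, weight_power: float = 4.0
) -> dict[str, list[PredictionResult]]:
    return {
        name: loo_population_predict(panel, name, M, weight_power=weight_power)
        for name in sorted({p.name for p in panel})
        if any(q.name != name for q in panel)
    }


# ---------------------------------------------------------------------------
# the loop


def curate_panel(
    panel: Sequence[ReferencePopulation],
    config: CurationConfig | None = None,
    oracle=None,
    seed: int = 0,
    regions: Mapping[str, str] | None = None,
) -> tuple[list[ReferencePopulation], CurationReport]:
    """Run the retention loop; returns (curated panel, per-round report).

    `oracle.distance_km(coordinate, region)` supplies the geography;
    `regions` maps parent population names to region ids (identity when
    omitted, i.e. one region per population). Correct assignment uses the
    same oracle and the `retain_km` threshold as retention.
    """
    config = config or CurationConfig()
    config.validate()
    if oracle is None:
        raise InputError("curation requires a region oracle")
    panel = list(panel)
    if not panel:
        raise InputError("reference panel is empty")
    regions = dict(regions) if regions is not None else {p.name: p.name for p in panel}

    report = CurationReport(ratio_mode=config.ratio_mode)
    current = _resplit(panel, config, seed)
    for rnd in range(1, config.max_rounds + 1):
        loo = _loo_all(current, config.n_neighbors)
        keep_ids: set[str] = set()
        n_total = n_correct = 0
        for name, results in loo.items():
            region = regions.get(name, name)
            for r in results:
                n_total += 1
                if oracle.distance_km(r.coordinate, region) < config.retain_km:
                    n_correct += 1
                    keep_ids.add(r.individual_id)
        if n_total == 0:
            raise InputError("leave-one-out produced no predictions (single-population panel?)")
        accuracy = n_correct / n_total
        report.accuracy_trace.append(accuracy)
        report.removed_per_round.append(n_total - n_correct)
        report.populations_per_round.append(len(current))
        report.n_rounds = rnd

        retained: list[ReferencePopulation] = []
        for pop in current:
            sel = [i for i, mid in enumerate(pop.member_ids) if mid in keep_ids]
            if len(sel) <= config.min_cluster_size:
                continue  # populations must keep more than four members to survive
            retained.append(
                ReferencePopulation(
                    name=pop.name,
                    location=pop.location,
                    members=pop.members[sel],
                    member_ids=[pop.member_ids[i] for i in sel],
                    subpopulation=pop.subpopulation,
                )
            )
        if not retained:
            raise InputError("curation round would empty the panel; aborting")
        current = _resplit(retained, config, seed + 1000 * rnd)

        if accuracy > config.target_accuracy:
            report.converged = True
            break
    return current, report


class PanelCurator(BaseEstimator):
    """Scikit-learn-style wrapper around :func:`curate_panel`.

    ``fit(panel, oracle=..., regions=...)`` runs the loop and exposes
    ``panel_``, ``report_``, ``accuracy_trace_`` and ``converged_``.
    """

    def __init__(
        self,
        accept_ratio: float = 0.9,
        ratio_mode: str = "accept_above",
        retain_km: float = 200.0,
        target_accuracy: float = 0.8,
        max_rounds: int = 10,
        n_neighbors: int = 10,
        kmeans_replications: int = 5,
        min_cluster_size: int = 4,
        random_state: int = 0,
    ):
        self.accept_ratio = accept_ratio
        self.ratio_mode = ratio_mode
        self.retain_km = retain_km
        self.target_accuracy = target_accuracy
        self.max_rounds = max_rounds
        self.n_neighbors = n_neighbors
        self.kmeans_replications = kmeans_replications
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def _config(self) -> CurationConfig:
        return CurationConfig(
            accept_ratio=self.accept_ratio,
            ratio_mode=self.ratio_mode,
            retain_km=self.retain_km,
            target_accuracy=self.target_accuracy,
            max_rounds=self.max_rounds,
            n_neighbors=self.n_neighbors,
            kmeans_replications=self.kmeans_replications,
            min_cluster_size=self.min_cluster_size,
        )

    def fit(self, panel, y=None, *, oracle=None, regions=None):
        self.panel_, self.report_ = curate_panel(
            panel, self._config(), oracle=oracle, seed=self.random_state, regions=regions
        )
        self.accuracy_trace_ = list(self.report_.accuracy_trace)
        self.converged_ = self.report_.converged
        return self
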