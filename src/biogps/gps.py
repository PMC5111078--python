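"""Admixture-to-geography conversion (the GPS algorithm).

An individual's genome is summarised by a length-K vector of admixture
proportions q (one proportion per putative ancestral population, unit sum).
Reference populations with known sampling locations carry the same K
proportions; the geographic position of a test individual is inferred by
matching q against the reference centroids, converting genetic distance to
kilometres with a locally fitted scaling, and taking a weighted spherical
mean of the nearest reference locations.

The prediction contract, in order of precedence:

* a test vector equal to a reference centroid is predicted exactly at that
  population's location (zero-distance fixed point);
* a 50/50 mixture of two mutually-nearest reference populations is predicted
  near the great-circle midpoint of their locations (mixed-origin contract,
  "mean geographical locations of the immediate parental populations").

Concretely, with GEN_i the Euclidean distance between q and centroid i and
the M nearest populations selected (ties broken by population name):

* weights w_i = (GEN_best / GEN_i)**p with sharpening exponent p (default 4);
* the geographic scaling lambda is the slope of the through-origin
  least-squares fit of great_circle_km(best, i) on (GEN_i - GEN_best);
* the predicted point is the weighted spherical mean of the selected
  locations, pulled back toward the best match so the displacement from the
  best match never exceeds lambda times the weighted mean genetic distance
  (which caps extrapolation beyond the panel hull while leaving symmetric
  mixtures free to reach the parental midpoint).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DomainError, InputError, ShapeError

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "ReferencePopulation",
    "PredictionResult",
    "GeographicPositioning",
    "admixture_distance",
    "great_circle_km",
    "gps_predict",
    "assignment_accuracy",
    "SiteRegionOracle",
    "GeoJSONRegionOracle",
]


# ---------------------------------------------------------------------------
# spherical geometry helpers


def _check_coordinate(coord) -> tuple[float, float]:
    lat, lon = float(coord[0]), float(coord[1])
    if not (-90.0 <= lat <= 90.0):
        raise DomainError(f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise DomainError(f"longitude {lon} outside [-180, 180]")
    return lat, lon


def great_circle_km(a, b) -> float:
    """Haversine great-circle distance in km on a sphere of radius 6371.0088.

    Parameters are (lat, lon) pairs in decimal degrees (WGS84 convention).
    """
    lat1, lon1 = _check_coordinate(a)
    lat2, lon2 = _check_coordinate(b)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    h = min(1.0, h)
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def _unit_vector(coord) -> np.ndarray:
    lat, lon = math.radians(coord[0]), math.radians(coord[1])
    return np.array(
        [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon), math.sin(lat)]
    )


def _vector_to_coord(v: np.ndarray) -> tuple[float, float]:
    x, y, z = v / np.linalg.norm(v)
    lat = math.degrees(math.asin(max(-1.0, min(1.0, z))))
    lon = math.degrees(math.atan2(y, x))
    return lat, lon


def _move_toward(origin, target, distance_km: float) -> tuple[float, float]:
    """Point at `distance_km` from origin along the great circle to target."""
    u = _unit_vector(origin)
    v = _unit_vector(target)
    total = great_circle_km(origin, target)
    if total <= 1e-12:
        return float(origin[0]), float(origin[1])
    t = distance_km / total
    omega = total / EARTH_RADIUS_KM  # angle between the unit vectors
    so = math.sin(omega)
    if so <= 1e-15:
        return float(origin[0]), float(origin[1])
    w = (math.sin((1.0 - t) * omega) / so) * u + (math.sin(t * omega) / so) * v
    return _vector_to_coord(w)


# ---------------------------------------------------------------------------
# admixture-space containers


def _as_simplex(q, *, atol: float = 1e-6, renorm: bool = True) -> np.ndarray:
    q = np.asarray(q, dtype=float).ravel()
    if q.size < 1:
        raise ShapeError("admixture vector is empty")
    if np.any(q < -1e-12):
        raise DomainError("admixture proportions must be non-negative")
    s = q.sum()
    if abs(s - 1.0) > atol:
        raise DomainError(f"admixture proportions sum to {s:.6g}, not 1")
    return q / s if renorm and s > 0 else q


def admixture_distance(q1, q2) -> float:
    """Euclidean distance between two admixture-proportion vectors."""
    q1 = np.asarray(q1, dtype=float).ravel()
    q2 = np.asarray(q2, dtype=float).ravel()
    if q1.shape != q2.shape:
        raise ShapeError(f"admixture vectors of unequal length: {q1.size} vs {q2.size}")
    return float(np.linalg.norm(q1 - q2))


@dataclass
class ReferencePopulation:
    """A named reference population with a sampling location and members.

    `name` is the parent population label; `subpopulation` is an optional
    sub-cluster tag (subpopulations of one parent share the parent label for
    leave-one-out exclusion). The matching target is the centroid — the
    arithmetic mean of member admixture vectors, re-normalised to the simplex.
    """

    name: str
    location: tuple[float, float]
    members: np.ndarray  # (n_members, K)
    member_ids: list[str] = field(default_factory=list)
    subpopulation: str | None = None

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        if self.members.shape[0] < 1:
            raise InputError(f"population {self.name!r} has no members")
        self.location = _check_coordinate(self.location)
        if not self.member_ids:
            self.member_ids = [f"{self.label}:{i}" for i in range(self.members.shape[0])]
        elif len(self.member_ids) != self.members.shape[0]:
            raise ShapeError(f"population {self.name!r}: member_ids/members length mismatch")

    @property
    def label(self) -> str:
        return self.name if self.subpopulation is None else f"{self.name}_{self.subpopulation}"

    @property
    def n_members(self) -> int:
        return int(self.members.shape[0])

    @property
    def n_components(self) -> int:
        return int(self.members.shape[1])

    @property
    def centroid(self) -> np.ndarray:
        c = self.members.mean(axis=0)
        s = c.sum()
        return c / s if s > 0 else c


@dataclass
class PredictionResult:
    """Inferred coordinates for one individual plus the evidence trail."""

    individual_id: str
    coordinate: tuple[float, float]
    nearest: list[tuple[str, float]]  # (population label, admixture distance), ascending
    best_match: str
    flags: set[str] = field(default_factory=set)

    @property
    def latitude(self) -> float:
        return self.coordinate[0]

    @property
    def longitude(self) -> float:
        return self.coordinate[1]


# ---------------------------------------------------------------------------
# prediction


def gps_predict(
    q,
    panel: Sequence[ReferencePopulation],
    M: int = 10,
    *,
    weight_power: float = 4.0,
    individual_id: str = "",
) -> PredictionResult:
    """Predict geographic coordinates for one admixture vector.

    See the module docstring for the algorithm. Deterministic given inputs;
    ties in centroid distance are broken by lexicographic population label.
    """
    panel = list(panel)
    if not panel:
        raise InputError("reference panel is empty")
    q = _as_simplex(q)
    K = q.size
    for pop in panel:
        if pop.n_components != K:
            raise ShapeError(
                f"panel population {pop.label!r} has K={pop.n_components}, test vector K={K}"
            )

    flags: set[str] = set()
    entries = sorted(
        ((admixture_distance(q, pop.centroid), pop.label, pop) for pop in panel),
        key=lambda e: (e[0], e[1]),
    )
    dists = [e[0] for e in entries]
    if len(dists) > 1 and any(
        abs(dists[i] - dists[i + 1]) < 1e-15 for i in range(len(dists) - 1)
    ):
        flags.add("tie_broken")
    if len(panel) < M:
        flags.add("fewer_than_M")
    sel = entries[: min(M, len(entries))]
    nearest = [(label, d) for d, label, _ in sel]
    best_d, best_label, best_pop = sel[0]

    if best_d <= 1e-12:
        return PredictionResult(individual_id, best_pop.location, nearest, best_label, flags)

    gen = np.array([d for d, _, _ in sel])
    w = (best_d / gen) ** weight_power
    wn = w / w.sum()

    # geographic scaling: through-origin fit of km(best, i) on (GEN_i - GEN_best)
    x = gen[1:] - best_d
    y = np.array([great_circle_km(best_pop.location, p.location) for _, _, p in sel[1:]])
    sxx = float(np.dot(x, x))
    lam = float(np.dot(x, y) / sxx) if sxx > 0 else 0.0

    mean_vec = np.sum(
        wn[:, None] * np.array([_unit_vector(p.location) for _, _, p in sel]), axis=0
    )
    if np.linalg.norm(mean_vec) <= 1e-12:
        # antipodal degenerate weighting; fall back to the best match
        flags.add("degenerate_mean")
        return PredictionResult(individual_id, best_pop.location, nearest, best_label, flags)
    target = _vector_to_coord(mean_vec)

    displacement = great_circle_km(best_pop.location, target)
    cap = lam * float(np.dot(wn, gen))
    coord = _move_toward(best_pop.location, target, min(max(cap, 0.0), displacement))
    return PredictionResult(individual_id, coord, nearest, best_label, flags)


class GeographicPositioning(BaseEstimator):
    """Nearest-reference-population coordinate predictor.

    Scikit-learn style estimator: ``fit(X, y, populations=...)`` with X the
    (n_members, K) matrix of reference admixture proportions, y the
    (n_members, 2) array of (lat, lon) sampling locations and ``populations``
    the per-member population labels; or ``fit_panel(panel)`` with ready-made
    :class:`ReferencePopulation` objects. ``predict(Q)`` returns an (n, 2)
    array of predicted coordinates; ``predict_result`` returns the full
    evidence trail per individual.

    Parameters
    ----------
    n_neighbors : int, default 10
        Number of nearest reference populations (M) used for the conversion.
    weight_power : float, default 4.0
        Sharpening exponent p applied to the distance-ratio weights.
    """

    def __init__(self, n_neighbors: int = 10, weight_power: float = 4.0):
        self.n_neighbors = n_neighbors
        self.weight_power = weight_power

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, populations=None, subpopulations=None, member_ids=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        n = X.shape[0]
        if y.shape != (n, 2):
            raise ShapeError(f"y must be (n, 2) lat/lon array, got {y.shape}")
        if populations is None:
            populations = [f"pop{i}" for i in range(n)]
        populations = list(map(str, populations))
        if len(populations) != n:
            raise ShapeError("populations length does not match X")
        if subpopulations is None:
            subpopulations = [None] * n
        if member_ids is None:
            member_ids = [f"{populations[i]}:{i}" for i in range(n)]
        groups: dict[tuple[str, str | None], list[int]] = {}
        for i, key in enumerate(zip(populations, subpopulations)):
            groups.setdefault(key, []).append(i)
        panel = []
        for (name, sub), idx in groups.items():
            locs = y[idx]
            if not np.allclose(locs, locs[0]):
                raise InputError(f"population {name!r} members carry inconsistent locations")
            panel.append(
                ReferencePopulation(
                    name=name,
                    location=(float(locs[0, 0]), float(locs[0, 1])),
                    members=X[idx],
                    member_ids=[member_ids[i] for i in idx],
                    subpopulation=sub,
                )
            )
        return self.fit_panel(panel)

    def fit_panel(self, panel: Iterable[ReferencePopulation]):
        """Fit directly from a list of :class:`ReferencePopulation`."""
        panel = list(panel)
        if not panel:
            raise InputError("reference panel is empty")
        K = panel[0].n_components
        for pop in panel:
            if pop.n_components != K:
                raise ShapeError("inconsistent K across panel populations")
        self.panel_ = panel
        self.n_components_ = K
        return self

    # -- prediction -------------------------------------------------------
    def predict_result(self, Q, ids=None) -> list[PredictionResult]:
        self._check_fitted()
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if ids is None:
            ids = [f"ind{i}" for i in range(Q.shape[0])]
        return [
            gps_predict(
                q,
                self.panel_,
                self.n_neighbors,
                weight_power=self.weight_power,
                individual_id=str(ids[i]),
            )
            for i, q in enumerate(Q)
        ]

    def predict(self, Q) -> np.ndarray:
        """Predicted (lat, lon) for each row of Q; shape (n, 2)."""
        return np.array([r.coordinate for r in self.predict_result(Q)])

    def _check_fitted(self) -> None:
        if not hasattr(self, "panel_"):
            raise InputError("GeographicPositioning instance is not fitted yet")


# ---------------------------------------------------------------------------
# region oracles & accuracy


class SiteRegionOracle:
    """Region membership by distance to the region's recorded sampling sites.

    A region (a country stand-in) is a set of (lat, lon) sites; the distance
    of a coordinate to the region is the minimum great-circle distance to any
    site, so a coordinate at a site is "inside" (0 km). An approximation of
    political borders usable without external geometry.
    """

    def __init__(self, region_sites: Mapping[str, Sequence[tuple[float, float]]]):
        if not region_sites:
            raise InputError("region oracle needs at least one region")
        self._sites = {
            str(r): [(_check_coordinate(s)) for s in sites] for r, sites in region_sites.items()
        }

    @property
    def regions(self) -> list[str]:
        return list(self._sites)

    def distance_km(self, coordinate, region: str) -> float:
        try:
            sites = self._sites[str(region)]
        except KeyError:
            raise InputError(f"unknown region {region!r}") from None
        return min(great_circle_km(coordinate, s) for s in sites)


class GeoJSONRegionOracle:
    """Region membership from polygons in a GeoJSON FeatureCollection.

    Each feature must carry the region id under ``properties[name_key]`` with
    (lon, lat) Polygon/MultiPolygon coordinates. Inside a polygon the distance
    is 0; outside, the planar degree distance to the boundary is converted to
    km at the latitude of the query point (small-distance approximation).
    Requires shapely.
    """

    def __init__(self, geojson: Mapping, name_key: str = "name"):
        from shapely.geometry import shape  # optional dependency

        self._shapes = {}
        for feat in geojson.get("features", []):
            name = str(feat.get("properties", {}).get(name_key))
            self._shapes[name] = shape(feat["geometry"])
        if not self._shapes:
            raise InputError("GeoJSON contains no regions")

    def distance_km(self, coordinate, region: str) -> float:
        from shapely.geometry import Point

        lat, lon = _check_coordinate(coordinate)
        try:
            geom = self._shapes[str(region)]
        except KeyError:
            raise InputError(f"unknown region {region!r}") from None
        p = Point(lon, lat)
        if geom.contains(p) or geom.touches(p):
            return 0.0
        ddeg = geom.distance(p)
        km_per_deg = math.pi * EARTH_RADIUS_KM / 180.0
        return ddeg * km_per_deg * math.sqrt((1.0 + math.cos(math.radians(lat)) ** 2) / 2.0)


def assignment_accuracy(
    predictions: Sequence[PredictionResult],
    truth: Mapping[str, str],
    oracle,
    thresholds_km: Sequence[float] = (250.0, 500.0),
) -> dict[float, float]:
    """Fraction of individuals predicted within each threshold of their region.

    ``truth`` maps individual id to region id; the oracle maps (coordinate,
    region) to a distance in km with 0 meaning inside. "Within t km" is
    inclusive. Returns {threshold: proportion}.
    """
    predictions = list(predictions)
    if not predictions:
        raise InputError("no predictions to score")
    dists = []
    for p in predictions:
        if p.individual_id not in truth:
            raise InputError(f"individual {p.individual_id!r} has no truth region")
        dists.append(oracle.distance_km(p.coordinate, truth[p.individual_id]))
    dists = np.asarray(dists)
    return {float(t): float(np.mean(dists <= float(t))) for t in thresholds_km}
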