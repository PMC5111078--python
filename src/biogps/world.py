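"""Synthetic worlds with genome-geography parallelism.

Generates reference panels, individuals and genotypes under the statistical
structure the biogeographic analysis assumes: K ancestral components anchored
at geographic source points, expected admixture at a location x decaying with
great-circle distance to each source,

    alpha_k(x)  proportional to  exp(-d(x, s_k) / tau),

individual vectors drawn Dirichlet(c * alpha(x)) around the local expectation
(c controls within-population noise), ancestral allele frequencies drawn
Beta(a, b) independently per component and locus, and genotypes drawn
Binomial(2, sum_k q_k f_kj) per locus under the linear-mixture model. Loci are
independent — no linkage structure is simulated.

Populations sit on a deterministic grid inside a bounding box (or at supplied
or random locations); grid populations are grouped into 2x2 blocks that act
as multi-site "countries" for the region oracle used in retention/accuracy
scoring. A single integer seed drives one documented generator stream with
per-entity sub-streams, so equal seeds give byte-identical worlds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .gps import ReferencePopulation, SiteRegionOracle, great_circle_km

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "make_world",
    "expected_admixture",
    "make_admixed_individual",
    "MISSING",
]

#: sentinel for a missing genotype in integer genotype matrices
MISSING = -1

_DEFAULT_BBOX = (10.0, 50.0, 20.0, 80.0)  # lat_min, lat_max, lon_min, lon_max


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    Defaults are the study conditions exercised throughout the test suite:
    30 populations of 20 individuals on a continental-scale grid (~4500 x
    5000 km), nine ancestral components, decay scale tau = 1000 km,
    Dirichlet concentration c = 50 and 10,000 independent loci.
    """

    n_components: int = 9
    component_sources: Sequence[tuple[float, float]] | None = None
    decay_scale_km: float = 1000.0
    concentration: float = 50.0
    n_populations: int = 30
    n_per_population: int = 20
    population_locations: Sequence[tuple[float, float]] | str | None = None
    bounding_box: tuple[float, float, float, float] = _DEFAULT_BBOX
    n_loci: int = 10_000
    beta_params: tuple[float, float] = (0.5, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_components < 2:
            raise ConfigurationError("n_components: K must be >= 2")
        if not self.decay_scale_km > 0:
            raise ConfigurationError("decay_scale_km: must be > 0")
        if not self.concentration > 0:
            raise ConfigurationError("concentration: must be > 0")
        if self.n_per_population < 1:
            raise ConfigurationError("n_per_population: must be >= 1")
        if self.n_populations < 1:
            raise ConfigurationError("n_populations: must be >= 1")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci: must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate: must be in [0, 1)")
        a, b = self.beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("beta_params: shape parameters must be > 0")
        lat0, lat1, lon0, lon1 = self.bounding_box
        if not (lat0 < lat1 and lon0 < lon1):
            raise ConfigurationError("bounding_box: requires lat_min < lat_max, lon_min < lon_max")
        if not (-90 <= lat0 and lat1 <= 90 and -180 <= lon0 and lon1 <= 180):
            raise ConfigurationError("bounding_box: coordinates out of range")
        if self.component_sources is not None and len(self.component_sources) != self.n_components:
            raise ConfigurationError("component_sources: need exactly K coordinates")
        if (
            self.population_locations is not None
            and not isinstance(self.population_locations, str)
            and len(self.population_locations) != self.n_populations
        ):
            raise ConfigurationError("population_locations: need exactly n_populations coordinates")


@dataclass
class SyntheticWorld:
    """A generated world: reference panel, individuals, and the truth behind them."""

    config: WorldConfig
    panel: list[ReferencePopulation]
    individual_ids: list[str]
    coordinates: np.ndarray  # (n, 2) true lat/lon per individual
    admixture: np.ndarray  # (n, K) true admixture vectors
    genotypes: np.ndarray  # (n, L) int8, values 0/1/2 or MISSING
    ancestral_freqs: np.ndarray  # (K, L) in (0, 1)
    population_of: dict[str, str]  # individual id -> population name
    region_of: dict[str, str]  # population name -> region id
    region_sites: dict[str, list[tuple[float, float]]]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def oracle(self) -> SiteRegionOracle:
        """Site-distance oracle over this world's regions."""
        return SiteRegionOracle(self.region_sites)

    def truth_regions(self) -> dict[str, str]:
        """Individual id -> region id (via its population)."""
        return {i: self.region_of[self.population_of[i]] for i in self.individual_ids}


def expected_admixture(
    location: tuple[float, float],
    sources: Sequence[tuple[float, float]],
    decay_scale_km: float,
) -> np.ndarray:
    """Expected admixture vector at a location: exp(-d/tau) per source, normalised."""
    d = np.array([great_circle_km(location, s) for s in sources])
    # subtract the min before exponentiating for numerical stability at small tau
    w = np.exp(-(d - d.min()) / decay_scale_km)
    return w / w.sum()


def make_admixed_individual(qa, qb, lam: float) -> np.ndarray:
    """Admixture vector of an individual with parents qa and qb: lam*qa + (1-lam)*qb."""
    if not (0.0 <= lam <= 1.0):
        raise DomainError(f"mixing proportion lam={lam} outside [0, 1]")
    qa = np.asarray(qa, dtype=float).ravel()
    qb = np.asarray(qb, dtype=float).ravel()
    if qa.shape != qb.shape:
        raise DomainError("parent vectors have different lengths")
    return lam * qa + (1.0 - lam) * qb


def _grid_locations(n: int, bbox: tuple[float, float, float, float]) -> tuple[list, list, list]:
    """Deterministic row-major grid of n points inside bbox.

    Returns (locations, row index, col index) so callers can derive region
    blocks from grid position.
    """
    lat0, lat1, lon0, lon1 = bbox
    nrows = max(1, int(round(math.sqrt(n * (lat1 - lat0) / max(lon1 - lon0, 1e-9)))))
    nrows = min(nrows, n)
    ncols = math.ceil(n / nrows)
    lat_pad = (lat1 - lat0) / (2 * nrows)
    lon_pad = (lon1 - lon0) / (2 * ncols)
    lats = np.linspace(lat0 + lat_pad, lat1 - lat_pad, nrows)
    lons = np.linspace(lon0 + lon_pad, lon1 - lon_pad, ncols)
    locs, rows, cols = [], [], []
    for i in range(n):
        r, c = divmod(i, ncols)
        locs.append((float(lats[r]), float(lons[c])))
        rows.append(r)
        cols.append(c)
    return locs, rows, cols


def _default_sources(K: int, bbox: tuple[float, float, float, float]) -> list[tuple[float, float]]:
    locs, _, _ = _grid_locations(K, bbox)
    return locs


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a synthetic world from a validated configuration.

    Deterministic: equal configs (including seed) give identical worlds.
    """
    config.validate()
    K, L = config.n_components, config.n_loci
    bbox = tuple(float(v) for v in config.bounding_box)

    ss = np.random.SeedSequence(config.seed)
    s_freqs, s_pops, s_missing = ss.spawn(3)
    rng_freqs = np.random.default_rng(s_freqs)

    sources = (
        [tuple(map(float, s)) for s in config.component_sources]
        if config.component_sources is not None
        else _default_sources(K, bbox)
    )

    # population locations and region blocks
    if config.population_locations is None:
        locs, rows, cols = _grid_locations(config.n_populations, bbox)
        regions = [f"R{r // 2}_{c // 2}" for r, c in zip(rows, cols)]
    elif isinstance(config.population_locations, str):
        if config.population_locations != "random":
            raise ConfigurationError(
                "population_locations: string form must be 'random'"
            )
        rng_loc = np.random.default_rng(ss.spawn(1)[0])
        lat0, lat1, lon0, lon1 = bbox
        locs = [
            (float(rng_loc.uniform(lat0, lat1)), float(rng_loc.uniform(lon0, lon1)))
            for _ in range(config.n_populations)
        ]
        regions = [f"P{i:02d}" for i in range(config.n_populations)]
    else:
        locs = [tuple(map(float, p)) for p in config.population_locations]
        regions = [f"P{i:02d}" for i in range(config.n_populations)]

    a, b = config.beta_params
    eps = 1e-6
    F = np.clip(rng_freqs.beta(a, b, size=(K, L)), eps, 1.0 - eps)

    pop_streams = s_pops.spawn(config.n_populations)
    panel: list[ReferencePopulation] = []
    ids: list[str] = []
    coords: list[tuple[float, float]] = []
    Q_rows: list[np.ndarray] = []
    G_rows: list[np.ndarray] = []
    population_of: dict[str, str] = {}

    for p in range(config.n_populations):
        rng = np.random.default_rng(pop_streams[p])
        name = f"P{p:02d}"
        loc = locs[p]
        alpha = expected_admixture(loc, sources, config.decay_scale_km)
        Q = rng.dirichlet(config.concentration * alpha, size=config.n_per_population)
        P = Q @ F
        G = rng.binomial(2, P).astype(np.int8)
        member_ids = [f"{name}_I{i:02d}" for i in range(config.n_per_population)]
        panel.append(
            ReferencePopulation(name=name, location=loc, members=Q, member_ids=member_ids)
        )
        for i, mid in enumerate(member_ids):
            ids.append(mid)
            coords.append(loc)
            Q_rows.append(Q[i])
            G_rows.append(G[i])
            population_of[mid] = name

    genotypes = np.vstack(G_rows).astype(np.int8)
    if config.missing_rate > 0:
        rng_m = np.random.default_rng(s_missing)
        mask = rng_m.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    region_of = {f"P{p:02d}": regions[p] for p in range(config.n_populations)}
    region_sites: dict[str, list[tuple[float, float]]] = {}
    for p in range(config.n_populations):
        region_sites.setdefault(regions[p], []).append(locs[p])

    return SyntheticWorld(
        config=config,
        panel=panel,
        individual_ids=ids,
        coordinates=np.asarray(coords, dtype=float),
        admixture=np.vstack(Q_rows),
        genotypes=genotypes,
        ancestral_freqs=F,
        population_of=population_of,
        region_of=region_of,
        region_sites=region_sites,
    )
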