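import numpy as np
import pytest

import biogps as bg


@pytest.fixture(scope="session")
def small_world() -> bg.SyntheticWorld:
    """A light synthetic world shared by read-only tests."""
    return bg.make_world(
        bg.WorldConfig(n_populations=12, n_per_population=8, n_loci=300, seed=3)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def twin_panel(noise: float = 0.0, seed: int = 0, n_members: int = 6):
    """Panel of co-located population twins with distinct admixture signatures.

    Each location hosts two populations with (near-)identical centroids, so a
    population-level leave-one-out prediction of either twin lands at the
    shared site: a panel in which every member is predicted at its own
    location. Returns (panel, regions, oracle).
    """
    rng = np.random.default_rng(seed)
    sites = [(20.0, 30.0), (25.0, 55.0), (42.0, 40.0), (38.0, 70.0)]
    base = np.array(
        [
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.85, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
            [0.05, 0.05, 0.05, 0.85],
        ]
    )
    panel, regions, region_sites = [], {}, {}
    for s, site in enumerate(sites):
        for twin in ("a", "b"):
            if noise > 0:
                members = rng.dirichlet(base[s] / noise, size=n_members)
            else:
                members = np.tile(base[s], (n_members, 1))
            name = f"S{s}{twin}"
            panel.append(
                bg.ReferencePopulation(
                    name=name,
                    location=site,
                    members=members,
                    member_ids=[f"{name}_m{i}" for i in range(n_members)],
                )
            )
            regions[name] = f"R{s}"
        region_sites[f"R{s}"] = [site]
    return panel, regions, bg.SiteRegionOracle(region_sites)
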