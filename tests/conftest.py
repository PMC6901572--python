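"""Shared fixtures: small, connected test layouts and canonical configs."""

import pytest

from endplatesim import (
    EndplateLayout,
    Occupant,
    RunConfig,
    Site,
    SiteKind,
    build_adjacency,
    build_layout,
)
from endplatesim.config import (
    CompositionConfig,
    ExecutionConfig,
    GeometryConfig,
)


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """A 30-site, 4-axon condition in a shrunken disc.

    The smaller region keeps the adjacency graph connected (30 sites in the
    full 300 px disc fall apart into tiny components).
    """
    return RunConfig(
        geometry=GeometryConfig(n_sites=30, region_diameter=170.0),
        composition=CompositionConfig(n_axons=4),
        execution=ExecutionConfig(max_iter=500_000, n_reps=4, base_seed=0),
    )


@pytest.fixture(scope="session")
def small_layout(small_config) -> EndplateLayout:
    return build_layout(small_config, seed=0)


def make_layout(
    occupants: list[Occupant],
    centers: list[tuple[float, float]],
    n_axons: int,
    site_diameter: float = 30.0,
    region_diameter: float = 300.0,
    neighbor_distance: float = 37.5,
) -> EndplateLayout:
    """Hand-built layout with explicit occupants and coordinates."""
    sites = [
        Site(site_id=i, center=c, radius=site_diameter / 2.0, occupant=o)
        for i, (o, c) in enumerate(zip(occupants, centers))
    ]
    layout = EndplateLayout(
        region_diameter=region_diameter,
        site_diameter=site_diameter,
        n_axons=n_axons,
        sites=sites,
        neighbor_distance=neighbor_distance,
    )
    layout.adjacency = build_adjacency(layout, neighbor_distance)
    return layout


@pytest.fixture
def axon_vacancy_cross():
    """A vacancy at the origin flanked by two axon-1 sites and one axon-2 site.

    All three axon sites are adjacent to the vacancy but not to each other
    (threshold 37.5 px), so the vacancy's axon neighbourhood holds axon 1
    twice and axon 2 once.
    """
    occupants = [
        Occupant(SiteKind.VACANCY),
        Occupant(SiteKind.AXON, 1),
        Occupant(SiteKind.AXON, 1),
        Occupant(SiteKind.AXON, 2),
    ]
    centers = [(0.0, 0.0), (30.0, 0.0), (-30.0, 0.0), (0.0, 30.0)]
    return make_layout(occupants, centers, n_axons=2)
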