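"""Endplate geometry: circular contact sites, their occupants, and adjacency.

The motor endplate is modelled as a round region tiled by identical circular
contact sites.  Each site is occupied by one of three classes — a terminal
Schwann cell (tSC), a vacancy, or an axon terminal carrying an axon identity.
Because all sites have the same diameter, site-count fractions equal area
fractions, and the measured area ratios of the three classes translate
directly into integer site counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SiteKind",
    "AreaRatios",
    "Occupant",
    "Site",
    "SiteCounts",
    "EndplateLayout",
    "ConfigurationError",
    "GeometryError",
    "apportion_site_counts",
    "place_sites",
    "build_adjacency",
    "layout_ratios",
    "LayoutComposition",
    "layout_to_json",
    "layout_from_json",
]

#: Default endplate diameter in pixels.
DEFAULT_REGION_DIAMETER = 300.0
#: Default contact-site diameter in pixels.
DEFAULT_SITE_DIAMETER = 30.0
#: Default minimum centre separation, as a fraction of the site diameter.
DEFAULT_MIN_SEPARATION_FACTOR = 0.8
#: Default adjacency threshold, as a fraction of the site diameter.
DEFAULT_NEIGHBOR_FACTOR = 1.25
#: Default number of distinct axons innervating a newborn endplate.
DEFAULT_N_AXONS = 9

_RATIO_TOL = 1e-6


class ConfigurationError(ValueError):
    """A site-count request that cannot be satisfied."""


class GeometryError(RuntimeError):
    """Site placement failed (the requested density is too high)."""


class SiteKind(IntEnum):
    """Occupant class of a contact site."""

    TSC = 0
    VACANCY = 1
    AXON = 2


@dataclass(frozen=True)
class AreaRatios:
    """Relative endplate coverage by tSCs, vacancies, and axons.

    The three fractions are the model's composition vector, ordered
    (tSC, vacancy, axon).  They must be non-negative and sum to one;
    percentage inputs can be normalised via :meth:`from_values`.

    Attributes
    ----------
    r_S, r_V, r_A
        Fractions of endplate area occupied by tSCs, vacancies, and axons
        (all axon identities pooled).
    """

    r_S: float
    r_V: float
    r_A: float

    def __post_init__(self) -> None:
        for name in ("r_S", "r_V", "r_A"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        total = self.r_S + self.r_V + self.r_A
        if abs(total - 1.0) > _RATIO_TOL:
            raise ValueError(
                f"ratios must sum to 1 (got {total!r}); "
                "use AreaRatios.from_values to normalise"
            )

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "AreaRatios":
        """Build normalised ratios from raw values (e.g. percentages)."""
        arr = np.asarray(values, dtype=float)
        if arr.shape != (3,):
            raise ValueError("expected exactly three values (tSC, vacancy, axon)")
        if np.any(arr < 0):
            raise ValueError("ratios must be non-negative")
        total = arr.sum()
        if total <= 0:
            raise ValueError("ratios must not all be zero")
        arr = arr / total
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))

    def as_array(self) -> np.ndarray:
        """Composition as an array ordered (tSC, vacancy, axon)."""
        return np.array([self.r_S, self.r_V, self.r_A])

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r_S, self.r_V, self.r_A)


@dataclass(frozen=True)
class Occupant:
    """What currently occupies a contact site.

    ``axon_id`` is defined exactly when ``kind`` is :attr:`SiteKind.AXON`;
    identities run from 1 to the layout's axon count.
    """

    kind: SiteKind
    axon_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind is SiteKind.AXON:
            if self.axon_id is None or self.axon_id < 1:
                raise ValueError("AXON occupants need a positive axon_id")
        elif self.axon_id is not None:
            raise ValueError(f"{self.kind.name} occupants carry no axon_id")


@dataclass
class Site:
    """One circular contact site: an id, a centre, a radius, an occupant."""

    site_id: int
    center: tuple[float, float]
    radius: float
    occupant: Occupant


@dataclass(frozen=True)
class SiteCounts:
    """Integer site counts per occupant category.

    ``axon_counts[k]`` is the number of sites initially given to axon
    identity ``k + 1``.
    """

    n_tsc: int
    n_vacancy: int
    axon_counts: tuple[int, ...]

    @property
    def n_axon(self) -> int:
        return sum(self.axon_counts)

    @property
    def total(self) -> int:
        return self.n_tsc + self.n_vacancy + self.n_axon


@dataclass
class EndplateLayout:
    """The simulation substrate: placed sites plus their adjacency relation.

    Site geometry is immutable during a simulation; only occupants change.
    ``adjacency`` maps each ``site_id`` to a sorted tuple of neighbouring
    site ids (symmetric, irreflexive).
    """

    region_diameter: float
    site_diameter: float
    n_axons: int
    sites: list[Site]
    adjacency: dict[int, tuple[int, ...]] = field(default_factory=dict)
    neighbor_distance: float | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.array([s.center for s in self.sites], dtype=float)

    def kinds(self) -> np.ndarray:
        return np.array([int(s.occupant.kind) for s in self.sites], dtype=np.int8)

    def axon_ids(self) -> np.ndarray:
        """Per-site axon identity (0 for non-axon sites)."""
        return np.array(
            [s.occupant.axon_id or 0 for s in self.sites], dtype=np.int32
        )


class LayoutComposition(NamedTuple):
    """Site-count fractions per category, with the axon pool broken out."""

    ratios: AreaRatios
    axon_fractions: dict[int, float]


def apportion_site_counts(
    ratios: AreaRatios, n_axons: int, n_sites: int
) -> SiteCounts:
    """Convert a composition vector into integer per-category site counts.

    Uses largest-remainder apportionment over the three categories, so each
    category's count differs from ``ratio * n_sites`` by less than one.  The
    axon pool is then split as evenly as possible across the ``n_axons``
    identities, with remainders assigned to the lowest ids (identities are
    exchangeable, and initial positions are shuffled, so this is bias-free).

    Raises
    ------
    ConfigurationError
        If ``n_sites < n_axons + 2`` or the axon pool cannot give every
        identity at least one site while ``r_A > 0``.
    """
    if n_axons < 1:
        raise ConfigurationError("n_axons must be >= 1")
    if n_sites < n_axons + 2:
        raise ConfigurationError(
            f"n_sites={n_sites} too small for n_axons={n_axons} (need >= n_axons + 2)"
        )
    quotas = ratios.as_array() * n_sites
    counts = np.floor(quotas).astype(int)
    remainder = n_sites - int(counts.sum())
    # ties broken by category order (tSC, vacancy, axon) for determinism
    order = sorted(range(3), key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:remainder]:
        counts[k] += 1
    n_tsc, n_vac, n_axon_sites = (int(c) for c in counts)
    if ratios.r_A > 0 and n_axon_sites < n_axons:
        raise ConfigurationError(
            f"{n_axon_sites} axon sites cannot cover {n_axons} axon identities; "
            "increase n_sites"
        )
    base, extra = divmod(n_axon_sites, n_axons)
    axon_counts = tuple(base + (1 if k < extra else 0) for k in range(n_axons))
    return SiteCounts(n_tsc, n_vac, axon_counts)


def _occupant_sequence(counts: SiteCounts) -> list[Occupant]:
    occ = [Occupant(SiteKind.TSC)] * counts.n_tsc
    occ += [Occupant(SiteKind.VACANCY)] * counts.n_vacancy
    for k, c in enumerate(counts.axon_counts, start=1):
        occ += [Occupant(SiteKind.AXON, k)] * c
    return occ


def _sample_in_disc(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _relax_positions(
    positions: np.ndarray,
    center_radius: float,
    separation: float,
    rng: np.random.Generator,
    max_sweeps: int,
) -> np.ndarray | None:
    """Resolve pairwise separation violations by iterated repulsion.

    Each sweep pushes every violating pair symmetrically apart toward a
    slightly inflated target distance (so converged distances clear the
    constraint despite rounding), then projects stray centres back onto the
    allowed disc.  Returns ``None`` if the configuration fails to satisfy
    the constraints within ``max_sweeps``.
    """
    P = positions.copy()
    target = separation * 1.05
    damp = 0.8
    for _ in range(max_sweeps):
        diff = P[:, None, :] - P[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        ii, jj = np.where(np.triu(dist < separation, 1))
        radii = np.linalg.norm(P, axis=1)
        if ii.size == 0 and np.all(radii <= center_radius + 1e-9):
            return P
        if ii.size:
            d = P[jj] - P[ii]
            pair = dist[ii, jj]
            degenerate = pair < 1e-9
            if degenerate.any():
                d[degenerate] = rng.normal(size=(int(degenerate.sum()), 2))
                pair = np.maximum(pair, 1e-9)
            push = (damp * (target - pair) / pair)[:, None] * d
            disp = np.zeros_like(P)
            np.add.at(disp, ii, -push)
            np.add.at(disp, jj, push)
            P = P + disp
        radii = np.linalg.norm(P, axis=1)
        outside = radii > center_radius
        if outside.any():
            P[outside] *= (center_radius / radii[outside])[:, None]
    return None


def place_sites(
    counts: SiteCounts,
    region_diameter: float = DEFAULT_REGION_DIAMETER,
    site_diameter: float = DEFAULT_SITE_DIAMETER,
    min_separation_factor: float = DEFAULT_MIN_SEPARATION_FACTOR,
    seed: int | np.random.Generator | None = None,
    neighbor_distance: float | None = None,
    max_attempts_per_site: int = 30,
    max_relax_sweeps: int = 20_000,
) -> EndplateLayout:
    """Randomly place the requested sites inside the endplate disc.

    Sites lie fully inside the region and keep pairwise centre distances of
    at least ``min_separation_factor * site_diameter`` (sites may therefore
    overlap mildly when the factor is below 1).  Placement first tries
    rejection sampling; at densities where that jams, a deterministic
    repulsion relaxation repairs the separation constraint.  Occupants from
    ``counts`` are assigned to the placed positions in a uniformly random
    permutation, so all categories are spatially interleaved at the start.

    Parameters
    ----------
    seed
        Integer seed or generator; placement is reproducible for a fixed
        seed.
    neighbor_distance
        Centre-distance threshold for the adjacency relation.  Defaults to
        1.25 x ``site_diameter``.

    Raises
    ------
    GeometryError
        When the requested density exceeds what the region can hold.
    """
    if not (0 < min_separation_factor <= 1):
        raise ValueError("min_separation_factor must be in (0, 1]")
    n = counts.total
    if n < 1:
        raise ConfigurationError("cannot place an empty layout")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    site_radius = site_diameter / 2.0
    center_radius = region_diameter / 2.0 - site_radius
    if center_radius < 0:
        raise GeometryError("site diameter exceeds region diameter")
    separation = min_separation_factor * site_diameter
    # hexagonal-packing upper bound on how many centres can keep the
    # required separation inside the allowed disc
    packing_density = (n * (separation / 2.0) ** 2) / (
        (center_radius + separation / 2.0) ** 2
    )
    if packing_density > 0.9069:
        raise GeometryError(
            f"cannot place {n} sites: requested density {packing_density:.3f} "
            "exceeds the hexagonal packing bound 0.907"
        )

    positions = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = max_attempts_per_site * n
    while placed < n and attempts < budget:
        p = _sample_in_disc(rng, center_radius)[0]
        if placed == 0 or np.all(
            np.hypot(positions[:placed, 0] - p[0], positions[:placed, 1] - p[1])
            >= separation
        ):
            positions[placed] = p
            placed += 1
        attempts += 1
    if placed < n:
        # rejection sampling jammed; seed the remainder randomly and relax
        positions[placed:] = _sample_in_disc(rng, center_radius, n - placed)
        relaxed = _relax_positions(
            positions, center_radius, separation, rng, max_relax_sweeps
        )
        if relaxed is None:
            raise GeometryError(
                f"placement of {n} sites at density {packing_density:.3f} "
                f"failed after {budget} rejection attempts and "
                f"{max_relax_sweeps} relaxation sweeps"
            )
        positions = relaxed

    occupants = _occupant_sequence(counts)
    perm = rng.permutation(n)  # occupant j goes to position perm[j]
    slot_occupant: dict[int, Occupant] = {
        int(perm[j]): occ for j, occ in enumerate(occupants)
    }
    sites = [
        Site(
            site_id=i,
            center=(float(positions[i, 0]), float(positions[i, 1])),
            radius=site_radius,
            occupant=slot_occupant[i],
        )
        for i in range(n)
    ]

    if neighbor_distance is None:
        neighbor_distance = DEFAULT_NEIGHBOR_FACTOR * site_diameter
    n_axons = len(counts.axon_counts)
    layout = EndplateLayout(
        region_diameter=region_diameter,
        site_diameter=site_diameter,
        n_axons=n_axons,
        sites=sites,
        neighbor_distance=neighbor_distance,
    )
    layout.adjacency = build_adjacency(layout, neighbor_distance)
    return layout


def build_adjacency(
    layout: EndplateLayout, neighbor_distance: float
) -> dict[int, tuple[int, ...]]:
    """Neighbour relation: sites are adjacent iff centres lie within a threshold.

    Symmetric and irreflexive.  Uses a k-d tree; equivalent to all-pairs
    thresholding of the centre distances.
    """
    if neighbor_distance <= 0:
        raise ValueError("neighbor_distance must be positive")
    pos = layout.positions()
    neighbors: dict[int, set[int]] = {s.site_id: set() for s in layout.sites}
    if len(layout.sites) > 1:
        tree = cKDTree(pos)
        for a, b in tree.query_pairs(neighbor_distance):
            ia, ib = layout.sites[a].site_id, layout.sites[b].site_id
            neighbors[ia].add(ib)
            neighbors[ib].add(ia)
    return {i: tuple(sorted(v)) for i, v in neighbors.items()}


def layout_ratios(layout: EndplateLayout) -> LayoutComposition:
    """Current composition of a layout as site-count fractions.

    All sites have identical area, so count fractions equal area fractions.
    """
    n = layout.n_sites
    if n == 0:
        raise ValueError("empty layout has no composition")
    kinds = layout.kinds()
    axon_ids = layout.axon_ids()
    r_s = float(np.sum(kinds == SiteKind.TSC)) / n
    r_v = float(np.sum(kinds == SiteKind.VACANCY)) / n
    r_a = float(np.sum(kinds == SiteKind.AXON)) / n
    axon_fracs = {
        k: float(np.sum(axon_ids == k)) / n for k in range(1, layout.n_axons + 1)
    }
    return LayoutComposition(AreaRatios(r_s, r_v, r_a), axon_fracs)


def layout_to_json(layout: EndplateLayout) -> str:
    """Serialise a layout snapshot to a JSON string (lossless round trip)."""
    record = {
        "region_diameter": layout.region_diameter,
        "site_diameter": layout.site_diameter,
        "n_axons": layout.n_axons,
        "neighbor_distance": layout.neighbor_distance,
        "sites": [
            {
                "site_id": s.site_id,
                "x": s.center[0],
                "y": s.center[1],
                "kind": s.occupant.kind.name,
                "axon_id": s.occupant.axon_id,
            }
            for s in layout.sites
        ],
    }
    return json.dumps(record, indent=1)


def layout_from_json(text: str) -> EndplateLayout:
    """Rebuild a layout from its JSON snapshot (adjacency is recomputed)."""
    record = json.loads(text)
    radius = record["site_diameter"] / 2.0
    sites = [
        Site(
            site_id=int(entry["site_id"]),
            center=(float(entry["x"]), float(entry["y"])),
            radius=radius,
            occupant=Occupant(SiteKind[entry["kind"]], entry["axon_id"]),
        )
        for entry in record["sites"]
    ]
    layout = EndplateLayout(
        region_diameter=float(record["region_diameter"]),
        site_diameter=float(record["site_diameter"]),
        n_axons=int(record["n_axons"]),
        sites=sites,
        neighbor_distance=record.get("neighbor_distance"),
    )
    if layout.neighbor_distance is not None:
        layout.adjacency = build_adjacency(layout, layout.neighbor_distance)
    return layout
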