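"""Per-iteration stochastic site-transition dynamics and run control.

Each iteration selects one contact site (uniformly, or with active-axon
sites down-weighted) and applies one stochastic transition draw.  Three
model variants are supported:

``vacancy_mediated``
    The constant-probability chain solved from a target stationary
    composition.  Axon and tSC sites may only become vacancies; a vacancy
    becomes a tSC with probability P_VS, otherwise an axon whose identity
    is drawn in proportion to the number of adjacent sites each surviving
    axon holds (falling back to global site counts when the vacancy has no
    axon neighbour).  Completion: exactly one axon identity survives, with
    tSCs and vacancies still present.

``random`` / ``equal``
    Neighbour-adoption dynamics: a site can only be converted into (a copy
    of) one of its neighbours.  A uniformly chosen adjacent donor is
    adopted with the transition probability into the donor's class, taken
    from a row that is either freshly random (uniform on the simplex,
    redrawn every step) or fixed at 1/3.  Completion: the layout is
    homogeneous (one axon identity everywhere, all tSC, or all vacant);
    homogeneous layouts are absorbing.

Every call to a step operation counts as one iteration, including draws
that leave the site unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .geometry import EndplateLayout, SiteKind
from .markov import GeneralProbs, VacancyMediatedProbs, sample_random_probs

__all__ = [
    "ActivityConfig",
    "SimulationState",
    "SimulationResult",
    "Event",
    "ALL_TSC",
    "ALL_VACANT",
    "NONE",
    "VACANCY_MEDIATED",
    "RANDOM",
    "EQUAL",
    "select_site",
    "step_vacancy_mediated",
    "step_neighbor_adoption",
    "is_complete",
    "run",
]

# model variants
VACANCY_MEDIATED = "vacancy_mediated"
RANDOM = "random"
EQUAL = "equal"

# terminal classes for runs that do not end with a single surviving axon id
ALL_TSC = "ALL_TSC"
ALL_VACANT = "ALL_VACANT"
NONE = "NONE"

_TSC = int(SiteKind.TSC)
_VAC = int(SiteKind.VACANCY)
_AXON = int(SiteKind.AXON)


class Event(NamedTuple):
    """One occupant change: (iteration, site, old kind/axon, new kind/axon)."""

    iteration: int
    site_id: int
    old_kind: int
    old_axon: int
    new_kind: int
    new_axon: int


@dataclass(frozen=True)
class ActivityConfig:
    """Activity bias: sites of active axons are selected less often.

    ``selection_divisor`` is the factor by which an active-axon site's
    selection weight is reduced (the default 2 halves it, i.e. an active
    site has a two-fold lower chance of undergoing a transition).
    """

    active_axon_ids: frozenset[int] = frozenset()
    selection_divisor: float = 2.0

    def __post_init__(self) -> None:
        if self.selection_divisor < 1.0:
            raise ValueError("selection_divisor must be >= 1")
        if any(a < 1 for a in self.active_axon_ids):
            raise ValueError("axon ids must be positive")

    @classmethod
    def none(cls) -> "ActivityConfig":
        return cls(frozenset(), 2.0)

    @classmethod
    def of(cls, ids: Iterable[int], selection_divisor: float = 2.0) -> "ActivityConfig":
        return cls(frozenset(int(i) for i in ids), selection_divisor)


class _UniformStream:
    """Buffered uniform variates from a Generator (fast scalar draws)."""

    __slots__ = ("generator", "_buf", "_i", "_block")

    def __init__(self, generator: np.random.Generator, block: int = 8192):
        self.generator = generator
        self._block = block
        self._buf = generator.random(block)
        self._i = 0

    def random(self) -> float:
        i = self._i
        if i == self._block:
            self._buf = self.generator.random(self._block)
            i = 0
        self._i = i + 1
        return self._buf[i]


class _GeneratorStream:
    """Unbuffered adapter giving a plain Generator the stream interface."""

    __slots__ = ("generator",)

    def __init__(self, generator: np.random.Generator):
        self.generator = generator

    def random(self) -> float:
        return self.generator.random()


def _as_stream(rng):
    if isinstance(rng, (_UniformStream, _GeneratorStream)):
        return rng
    if rng is None:
        return _GeneratorStream(np.random.default_rng())
    return _GeneratorStream(rng)


@dataclass
class SimulationState:
    """Mutable occupancy state over an immutable site geometry.

    Occupants are held as flat arrays for speed; per-axon site counts, the
    set of extinct axons, and the live-axon count are maintained
    incrementally.  Site count and geometry never change.
    """

    layout: EndplateLayout
    kinds: np.ndarray
    axon_ids: np.ndarray
    adjacency: list[np.ndarray]
    n_axons: int
    iteration: int = 0
    axon_site_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_alive_axons: int = 0
    extinct_axons: set[int] = field(default_factory=set)
    event_log: list[Event] | None = None

    @classmethod
    def from_layout(
        cls, layout: EndplateLayout, record_events: bool = False
    ) -> "SimulationState":
        kinds = layout.kinds().astype(np.int64)
        axon_ids = layout.axon_ids().astype(np.int64)
        adjacency = [
            np.asarray(layout.adjacency.get(s.site_id, ()), dtype=np.int64)
            for s in layout.sites
        ]
        n_axons = layout.n_axons
        ax_counts = np.bincount(
            axon_ids[kinds == _AXON], minlength=n_axons + 1
        ).astype(np.int64)
        kind_counts = np.bincount(kinds, minlength=3).astype(np.int64)
        alive = int(np.sum(ax_counts[1:] > 0))
        extinct = {k for k in range(1, n_axons + 1) if ax_counts[k] == 0}
        return cls(
            layout=layout,
            kinds=kinds,
            axon_ids=axon_ids,
            adjacency=adjacency,
            n_axons=n_axons,
            axon_site_counts=ax_counts,
            kind_counts=kind_counts,
            n_alive_axons=alive,
            extinct_axons=extinct,
            event_log=[] if record_events else None,
        )

    @property
    def n_sites(self) -> int:
        return len(self.kinds)

    def distinct_axon_count(self) -> int:
        return self.n_alive_axons

    def composition(self) -> tuple[float, float, float]:
        """Current (tSC, vacancy, axon) site fractions."""
        n = self.n_sites
        return (
            self.kind_counts[_TSC] / n,
            self.kind_counts[_VAC] / n,
            self.kind_counts[_AXON] / n,
        )

    def _apply(self, i: int, new_kind: int, new_axon: int) -> Event:
        old_kind = self.kinds[i]
        old_axon = self.axon_ids[i]
        self.kind_counts[old_kind] -= 1
        self.kind_counts[new_kind] += 1
        if old_kind == _AXON:
            self.axon_site_counts[old_axon] -= 1
            if self.axon_site_counts[old_axon] == 0:
                self.n_alive_axons -= 1
                self.extinct_axons.add(int(old_axon))
        if new_kind == _AXON:
            if self.axon_site_counts[new_axon] == 0:
                self.n_alive_axons += 1  # defensive; draws exclude extinct ids
            self.axon_site_counts[new_axon] += 1
        self.kinds[i] = new_kind
        self.axon_ids[i] = new_axon
        event = Event(
            self.iteration,
            i,
            int(old_kind),
            int(old_axon),
            int(new_kind),
            int(new_axon),
        )
        if self.event_log is not None:
            self.event_log.append(event)
        return event


@dataclass
class SimulationResult:
    """Outcome of one run.

    ``winner`` is the surviving axon id when ``completed``, or one of the
    terminal-class labels ``ALL_TSC`` / ``ALL_VACANT`` for homogeneous
    non-axon endpoints; ``NONE`` marks a run stopped at ``max_iter``.
    ``iterations`` is the least iteration index at which the completion
    condition held.
    """

    completed: bool
    iterations: int
    winner: int | str
    seed: object
    model: str
    n_sites: int
    active_axon_ids: tuple[int, ...] = ()
    series: list[tuple[int, float, float, float, int]] | None = None
    events: list[Event] | None = None

    def series_rows(self) -> list[dict]:
        if self.series is None:
            return []
        return [
            {
                "iteration": it,
                "frac_tSC": fs,
                "frac_vac": fv,
                "frac_axon": fa,
                "n_axon_types": na,
            }
            for (it, fs, fv, fa, na) in self.series
        ]

    def event_rows(self) -> list[dict]:
        if self.events is None:
            return []
        return [e._asdict() for e in self.events]


def select_site(state: SimulationState, activity: ActivityConfig | None, rng) -> int:
    """Pick the site to undergo this iteration's transition draw.

    With no activity bias the choice is uniform.  With active axons, site i
    is chosen with probability w_i / sum(w), where w_i = 1/divisor for
    sites held by an active axon and 1 otherwise (implemented by rejection,
    which realises exactly those weights).
    """
    u = _as_stream(rng)
    n = state.n_sites
    if activity is None or not activity.active_axon_ids:
        return int(u.random() * n)
    accept = 1.0 / activity.selection_divisor
    kinds = state.kinds
    axon_ids = state.axon_ids
    active = activity.active_axon_ids
    while True:
        i = int(u.random() * n)
        if kinds[i] != _AXON or axon_ids[i] not in active:
            return i
        if u.random() < accept:
            return i


def _draw_weighted_axon(weights: np.ndarray, u: float) -> int:
    """Index (1-based axon id) drawn proportionally to ``weights[1:]``."""
    total = weights[1:].sum()
    if total <= 0:
        return 0
    r = u * total
    acc = 0
    for a in range(1, len(weights)):
        acc += weights[a]
        if r < acc:
            return a
    return len(weights) - 1


def step_vacancy_mediated(
    state: SimulationState,
    probs: VacancyMediatedProbs,
    activity: ActivityConfig | None = None,
    rng=None,
    select_rng=None,
) -> Event | None:
    """One iteration of the vacancy-mediated dynamics.

    Axon and tSC sites may only vacate (with p_AV / p_SV).  A selected
    vacancy becomes a tSC with p_VS, otherwise an axon site whose identity
    is drawn with probability proportional to the number of adjacent sites
    each surviving axon holds; a vacancy with no axon neighbour falls back
    to weights proportional to each surviving axon's total site count.
    Extinct axons have weight zero and can never be drawn; if no axon site
    exists anywhere, the vacancy stays vacant.

    ``select_rng`` optionally separates the site-selection stream from the
    transition stream.  Returns the applied :class:`Event`, or ``None`` for
    a no-transition draw.  Increments ``state.iteration`` either way.
    """
    u = _as_stream(rng)
    su = u if select_rng is None else _as_stream(select_rng)
    state.iteration += 1
    i = select_site(state, activity, su)
    k = state.kinds[i]
    if k == _AXON:
        if u.random() < probs.p_AV:
            return state._apply(i, _VAC, 0)
    elif k == _TSC:
        if u.random() < probs.p_SV:
            return state._apply(i, _VAC, 0)
    else:  # vacancy
        if u.random() < probs.p_VS:
            return state._apply(i, _TSC, 0)
        neighbors = state.adjacency[i]
        kinds = state.kinds
        axon_ids = state.axon_ids
        local = np.zeros(state.n_axons + 1, dtype=np.int64)
        found = False
        for j in neighbors:
            if kinds[j] == _AXON:
                local[axon_ids[j]] += 1
                found = True
        weights = local if found else state.axon_site_counts
        a = _draw_weighted_axon(weights, u.random())
        if a > 0:
            return state._apply(i, _AXON, a)
        # else: no surviving axon anywhere; the vacancy stays vacant
    return None


def step_neighbor_adoption(
    state: SimulationState,
    probs_source: str = RANDOM,
    rng=None,
    select_rng=None,
) -> Event | None:
    """One iteration of the random- or equal-probability dynamics.

    The selected site can only be converted into a site adjacent to it: a
    uniformly chosen neighbour acts as the donor, and the conversion is
    accepted with the selected site's transition probability into the
    donor's class — freshly sampled each step (``"random"``, every row
    uniform on the simplex) or fixed at one third (``"equal"``).  Accepted
    conversions copy the donor's class and, for axon donors, its identity;
    copying an identical occupant realises the no-transition outcome.
    Sites without neighbours never change, so homogeneous layouts are
    absorbing.
    """
    u = _as_stream(rng)
    su = u if select_rng is None else _as_stream(select_rng)
    state.iteration += 1
    n = state.n_sites
    i = int(su.random() * n)
    neighbors = state.adjacency[i]
    if len(neighbors) == 0:
        return None
    j = int(neighbors[int(u.random() * len(neighbors))])
    donor_kind = int(state.kinds[j])
    k = int(state.kinds[i])
    if probs_source == EQUAL:
        p = 1.0 / 3.0
    elif probs_source == RANDOM:
        gp: GeneralProbs = sample_random_probs(u.generator)
        p = float(gp.row(SiteKind(k))[donor_kind])
    else:
        raise ValueError(f"unknown probs_source {probs_source!r}")
    if u.random() >= p:
        return None
    donor_axon = int(state.axon_ids[j])
    if donor_kind == k and donor_axon == int(state.axon_ids[i]):
        return None  # copying an identical occupant: no transition
    return state._apply(i, donor_kind, donor_axon)


def is_complete(state: SimulationState, model: str) -> tuple[bool, int | str]:
    """Completion test and terminal class.

    Vacancy-mediated: complete iff exactly one axon identity holds at least
    one site (tSCs and vacancies may and normally do remain).  Neighbour-
    adoption models: complete iff the layout is homogeneous — all sites one
    axon identity, all tSC (``ALL_TSC``) or all vacant (``ALL_VACANT``).
    """
    if model == VACANCY_MEDIATED:
        if state.n_alive_axons == 1:
            winner = int(np.argmax(state.axon_site_counts[1:]) + 1)
            return True, winner
        return False, NONE
    n = state.n_sites
    if state.kind_counts[_TSC] == n:
        return True, ALL_TSC
    if state.kind_counts[_VAC] == n:
        return True, ALL_VACANT
    if state.kind_counts[_AXON] == n and state.n_alive_axons == 1:
        winner = int(np.argmax(state.axon_site_counts[1:]) + 1)
        return True, winner
    return False, NONE


_DEFAULT_MAX_ITER = {VACANCY_MEDIATED: 50_000, RANDOM: 10_000, EQUAL: 200_000}


def run(
    layout: EndplateLayout,
    model: str = VACANCY_MEDIATED,
    probs: VacancyMediatedProbs | None = None,
    activity: ActivityConfig | None = None,
    max_iter: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    record_series: bool = False,
    series_stride: int = 50,
    record_events: bool = False,
    stop_when_complete: bool = True,
) -> SimulationResult:
    """Iterate the chosen dynamics until completion or ``max_iter``.

    The run seed expands deterministically into separate selection and
    transition streams, so a run is fully reproducible from the layout seed
    plus the run seed.  Reaching ``max_iter`` is reported as
    ``completed=False`` with winner ``NONE``, never as an exception.

    Parameters
    ----------
    record_series
        Log (iteration, composition fractions, distinct-axon count) every
        ``series_stride`` iterations plus the initial and final states.
    stop_when_complete
        Set to False to keep iterating past completion (used to study the
        stationary composition); the result still reports the least
        completion iteration.
    """
    if model not in _DEFAULT_MAX_ITER:
        raise ValueError(f"unknown model {model!r}")
    if model == VACANCY_MEDIATED and probs is None:
        raise ValueError("vacancy_mediated runs need transition probabilities")
    if max_iter is None:
        max_iter = _DEFAULT_MAX_ITER[model]
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sel_ss, trans_ss = ss.spawn(2)
    sel_u = _UniformStream(np.random.default_rng(sel_ss))
    trans_u = _UniformStream(np.random.default_rng(trans_ss))

    state = SimulationState.from_layout(layout, record_events=record_events)
    series: list[tuple[int, float, float, float, int]] | None = (
        [] if record_series else None
    )

    def log_point() -> None:
        fs, fv, fa = state.composition()
        series.append((state.iteration, fs, fv, fa, state.n_alive_axons))

    if series is not None:
        log_point()

    completed, winner = is_complete(state, model)
    least_iter = 0 if completed else -1

    while state.iteration < max_iter:
        if completed and stop_when_complete:
            break
        if model == VACANCY_MEDIATED:
            step_vacancy_mediated(
                state, probs, activity, rng=trans_u, select_rng=sel_u
            )
        else:
            step_neighbor_adoption(state, model, rng=trans_u, select_rng=sel_u)
        if not completed:
            completed, winner = is_complete(state, model)
            if completed:
                least_iter = state.iteration
        if series is not None and (
            state.iteration % series_stride == 0 or (completed and stop_when_complete)
        ):
            log_point()

    if series is not None and series[-1][0] != state.iteration:
        log_point()
    active_ids = tuple(sorted(activity.active_axon_ids)) if activity else ()
    return SimulationResult(
        completed=completed,
        iterations=least_iter if completed else state.iteration,
        winner=winner if completed else NONE,
        seed=ss.entropy,
        model=model,
        n_sites=state.n_sites,
        active_axon_ids=active_ids,
        series=series,
        events=state.event_log,
    )
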