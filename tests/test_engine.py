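"""Step dynamics: site selection, transitions, termination, reproducibility."""


import numpy as np
import pytest

from endplatesim import (
    ALL_VACANT,
    NONE,
    ActivityConfig,
    Occupant,
    SimulationState,
    SiteKind,
    VacancyMediatedProbs,
    is_complete,
    run,
    select_site,
    step_neighbor_adoption,
    step_vacancy_mediated,
)


from conftest import make_layout

P3_PROBS = VacancyMediatedProbs(p_AV=0.288, p_SV=0.18 * 0.6 / 0.57, p_VS=0.6)


def ring_layout(occupants, radius=60.0, n_axons=9):
    n = len(occupants)
    centers = [
        (radius * np.cos(2 * np.pi * k / n), radius * np.sin(2 * np.pi * k / n))
        for k in range(n)
    ]
    return make_layout(occupants, centers, n_axons=n_axons)


class TestSelectSite:
    def test_uniform_without_activity(self):
        occupants = [Occupant(SiteKind.TSC)] * 5 + [Occupant(SiteKind.VACANCY)] * 5
        layout = ring_layout(occupants)
        state = SimulationState.from_layout(layout)
        rng = np.random.default_rng(0)
        n_draws = 100_000
        counts = np.bincount(
            [select_site(state, None, rng) for _ in range(n_draws)], minlength=10
        )
        # each site has p = 0.1; allow 4 Monte-Carlo SDs
        tol = 4 * np.sqrt(0.1 * 0.9 / n_draws)
        assert np.all(np.abs(counts / n_draws - 0.1) < tol)

    def test_active_axon_sites_half_weight(self):
        occupants = (
            [Occupant(SiteKind.AXON, 1)] * 2
            + [Occupant(SiteKind.AXON, 2)] * 3
            + [Occupant(SiteKind.TSC)] * 3
            + [Occupant(SiteKind.VACANCY)] * 2
        )
        layout = ring_layout(occupants)
        state = SimulationState.from_layout(layout)
        activity = ActivityConfig.of([1], selection_divisor=2.0)
        rng = np.random.default_rng(1)
        n_draws = 100_000
        counts = np.bincount(
            [select_site(state, activity, rng) for _ in range(n_draws)],
            minlength=10,
        )
        freqs = counts / n_draws
        # weights: two active sites at 0.5, eight others at 1 -> total 9
        expected = np.array([0.5 / 9] * 2 + [1 / 9] * 8)
        tol = 4 * np.sqrt(expected * (1 - expected) / n_draws)
        assert np.all(np.abs(freqs - expected) < tol)


class TestVacancyMediatedStep:
    def test_reclaim_weighted_by_adjacent_sites(self, axon_vacancy_cross):
        """V->A identity follows local site counts: axon 1 twice, axon 2 once."""
        probs = VacancyMediatedProbs(p_AV=0.0, p_SV=0.0, p_VS=0.0)
        rng = np.random.default_rng(2)
        wins = {1: 0, 2: 0}
        n_events = 0
        while n_events < 20_000:
            state = SimulationState.from_layout(axon_vacancy_cross)
            event = step_vacancy_mediated(state, probs, rng=rng)
            if event is not None:
                wins[event.new_axon] += 1
                n_events += 1
        frac1 = wins[1] / n_events
        tol = 4 * np.sqrt((2 / 3) * (1 / 3) / n_events)
        assert abs(frac1 - 2 / 3) < tol

    def test_reclaim_falls_back_to_global_counts(self):
        """A vacancy with no axon neighbour uses total-site-count weights."""
        occupants = [
            Occupant(SiteKind.VACANCY),
            Occupant(SiteKind.AXON, 1),
            Occupant(SiteKind.AXON, 1),
            Occupant(SiteKind.AXON, 1),
            Occupant(SiteKind.AXON, 2),
        ]
        # vacancy far from every axon site; axons clustered at x ~ +200
        centers = [(-100.0, 0.0), (80.0, 0.0), (110.0, 0.0), (95.0, 26.0), (80.0, 30.0)]
        layout = make_layout(occupants, centers, n_axons=2)
        assert layout.adjacency[0] == ()
        probs = VacancyMediatedProbs(p_AV=0.0, p_SV=0.0, p_VS=0.0)
        rng = np.random.default_rng(3)
        wins = {1: 0, 2: 0}
        n_events = 0
        while n_events < 20_000:
            state = SimulationState.from_layout(layout)
            event = step_vacancy_mediated(state, probs, rng=rng)
            if event is not None:
                wins[event.new_axon] += 1
                n_events += 1
        frac1 = wins[1] / n_events
        tol = 4 * np.sqrt(0.75 * 0.25 / n_events)
        assert abs(frac1 - 0.75) < tol

    def test_no_transition_branch_counts_iteration(self):
        layout = ring_layout([Occupant(SiteKind.TSC)] * 6)
        state = SimulationState.from_layout(layout)
        probs = VacancyMediatedProbs(p_AV=0.5, p_SV=0.0, p_VS=0.5)
        event = step_vacancy_mediated(state, probs, rng=np.random.default_rng(0))
        assert event is None
        assert state.iteration == 1
        assert np.all(state.kinds == int(SiteKind.TSC))

    def test_extinct_axon_never_returns(self, small_config):
        from endplatesim import build_layout

        layout = build_layout(small_config, seed=1)
        result = run(
            layout,
            probs=P3_PROBS,
            seed=11,
            max_iter=500_000,
            record_events=True,
            record_series=True,
        )
        assert result.completed
        # replay: extinction is absorbing
        counts = dict(
            zip(*np.unique(layout.axon_ids()[layout.kinds() == 2], return_counts=True))
        )
        extinct = set()
        for e in result.events:
            if e.old_kind == int(SiteKind.AXON):
                counts[e.old_axon] -= 1
                if counts[e.old_axon] == 0:
                    extinct.add(e.old_axon)
            if e.new_kind == int(SiteKind.AXON):
                assert e.new_axon not in extinct
                counts[e.new_axon] = counts.get(e.new_axon, 0) + 1
        # distinct-axon count is non-increasing along the recorded series
        series_counts = [pt[4] for pt in result.series]
        assert all(a >= b for a, b in zip(series_counts, series_counts[1:]))

    def test_no_direct_axon_tsc_exchange(self, small_config):
        from endplatesim import build_layout

        layout = build_layout(small_config, seed=2)
        result = run(
            layout, probs=P3_PROBS, seed=5, max_iter=200_000, record_events=True
        )
        A, S = int(SiteKind.AXON), int(SiteKind.TSC)
        for e in result.events:
            assert (e.old_kind, e.new_kind) not in {(A, S), (S, A)}


class TestNeighborAdoption:
    def test_all_vacant_layout_is_absorbing(self):
        layout = ring_layout([Occupant(SiteKind.VACANCY)] * 8)
        state = SimulationState.from_layout(layout)
        rng = np.random.default_rng(0)
        for _ in range(300):
            step_neighbor_adoption(state, "equal", rng=rng)
        assert np.all(state.kinds == int(SiteKind.VACANCY))
        complete, terminal = is_complete(state, "equal")
        assert complete and terminal == ALL_VACANT

    def test_one_step_kernel_matches_enumeration(self):
        """Exact one-step distribution on the 3-site path axon-vacancy-tSC."""
        occupants = [
            Occupant(SiteKind.AXON, 1),
            Occupant(SiteKind.VACANCY),
            Occupant(SiteKind.TSC),
        ]
        centers = [(-30.0, 0.0), (0.0, 0.0), (30.0, 0.0)]
        layout = make_layout(occupants, centers, n_axons=1)
        assert layout.adjacency == {0: (1,), 1: (0, 2), 2: (1,)}

        A, V, S = int(SiteKind.AXON), int(SiteKind.VACANCY), int(SiteKind.TSC)
        start = ((A, 1), (V, 0), (S, 0))

        # oracle: enumerate site choice x donor choice x accept(1/3)
        def enumerate_kernel():
            kernel: dict[tuple, float] = {}
            adjacency = {0: (1,), 1: (0, 2), 2: (1,)}
            for site in range(3):
                p_site = 1 / 3
                donors = adjacency[site]
                for donor in donors:
                    p_donor = p_site / len(donors)
                    nxt = list(start)
                    nxt[site] = start[donor]
                    accepted = tuple(nxt)
                    kernel[accepted] = kernel.get(accepted, 0.0) + p_donor * (1 / 3)
                    kernel[start] = kernel.get(start, 0.0) + p_donor * (2 / 3)
            return kernel

        kernel = enumerate_kernel()
        assert sum(kernel.values()) == pytest.approx(1.0)

        rng = np.random.default_rng(4)
        n_steps = 60_000
        observed: dict[tuple, int] = {}
        for _ in range(n_steps):
            state = SimulationState.from_layout(layout)
            step_neighbor_adoption(state, "equal", rng=rng)
            key = tuple(
                (int(k), int(a)) for k, a in zip(state.kinds, state.axon_ids)
            )
            observed[key] = observed.get(key, 0) + 1
        assert set(observed) <= set(kernel)
        for outcome, p in kernel.items():
            freq = observed.get(outcome, 0) / n_steps
            tol = 4 * np.sqrt(p * (1 - p) / n_steps) + 1e-9
            assert abs(freq - p) < tol, (outcome, freq, p)

    def test_terminal_classes_on_small_runs(self, small_config):
        from endplatesim import build_layout

        for model, seeds in (("equal", range(4)), ("random", range(4))):
            for sd in seeds:
                layout = build_layout(small_config, seed=sd)
                result = run(
                    layout, model=model, seed=100 + sd, max_iter=500_000,
                    record_series=True,
                )
                assert result.completed
                assert result.winner == ALL_VACANT or result.winner == "ALL_TSC" or (
                    isinstance(result.winner, int) and 1 <= result.winner <= 4
                )
                # terminal state is homogeneous: one fraction is exactly 1
                last = result.series[-1]
                assert max(last[1], last[2], last[3]) == pytest.approx(1.0)


class TestRunControl:
    def test_vacuous_completion(self):
        occupants = [Occupant(SiteKind.AXON, 3)] * 2 + [
            Occupant(SiteKind.TSC),
            Occupant(SiteKind.VACANCY),
        ]
        layout = ring_layout(occupants)
        result = run(layout, probs=P3_PROBS, seed=0)
        assert result.completed and result.iterations == 0 and result.winner == 3

    def test_max_iter_cap(self, small_layout):
        result = run(small_layout, probs=P3_PROBS, seed=0, max_iter=10)
        assert not result.completed
        assert result.iterations == 10
        assert result.winner == NONE

    def test_run_reproducibility_and_conservation(self, small_layout):
        kinds_before = small_layout.kinds().copy()
        a = run(small_layout, probs=P3_PROBS, seed=42, max_iter=500_000,
                record_series=True)
        b = run(small_layout, probs=P3_PROBS, seed=42, max_iter=500_000,
                record_series=True)
        c = run(small_layout, probs=P3_PROBS, seed=43, max_iter=500_000)
        assert a.iterations == b.iterations and a.winner == b.winner
        assert a.series == b.series
        assert (a.iterations, a.winner) != (c.iterations, c.winner)
        # the layout object itself is never mutated by a run
        assert np.array_equal(small_layout.kinds(), kinds_before)

    def test_completion_with_copresence(self, small_layout):
        """Vacancy-mediated completion keeps tSCs and vacancies around."""
        result = run(
            small_layout, probs=P3_PROBS, seed=9, max_iter=500_000,
            record_series=True,
        )
        assert result.completed
        last = result.series[-1]
        assert last[4] == 1  # one surviving axon identity
        assert last[1] > 0 and last[2] > 0  # tSC and vacancy fractions remain

    def test_is_complete_multiple_axons(self):
        occupants = [Occupant(SiteKind.AXON, 1), Occupant(SiteKind.AXON, 2)]
        layout = ring_layout(occupants)
        state = SimulationState.from_layout(layout)
        complete, terminal = is_complete(state, "vacancy_mediated")
        assert not complete and terminal == NONE
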