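"""Batch experiments: elimination-time distributions, activity and ratio sweeps.

These drivers wrap the engine into the study designs the model exists for:

* :func:`batch_run` — repeated independent runs of one condition, with the
  mean +/- SD of the least completion iteration and a per-winner table;
* :func:`stage_comparison` — the developmental-stage contrast (probabilities
  solved from the P3 / P7 / P16 compositions) with pairwise t-tests;
* :func:`activity_sweep` — winner selection and elimination rate as the
  number of active axons grows;
* :func:`ratio_sweep` — elimination rate across endplate-to-endplate
  composition variants, correlated (Spearman) with the composite area
  r_S * r_V / r_A.

All statistics are plain functions of the retained per-run results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .config import RunConfig, build_layout, resolve_probs
from .engine import ActivityConfig, SimulationResult, run
from .geometry import AreaRatios
from .markov import InfeasibleRatiosError, solve_stationary_probabilities

__all__ = [
    "STAGE_RATIOS",
    "RatioProfile",
    "ExperimentSummary",
    "ActivityOutcome",
    "RatioSweepResult",
    "StageComparisonResult",
    "composite_area",
    "batch_run",
    "activity_sweep",
    "ratio_sweep",
    "stage_comparison",
    "generate_ratio_variants",
]

logger = logging.getLogger(__name__)

#: Measured mean contact-area ratios (tSC, vacancy, axon) by postnatal day.
STAGE_RATIOS: dict[str, AreaRatios] = {
    "P0": AreaRatios.from_values((31, 17, 52)),
    "P3": AreaRatios.from_values((57, 18, 25)),
    "P7": AreaRatios.from_values((55, 5, 40)),
    "P16": AreaRatios.from_values((41, 6, 53)),
}


def composite_area(ratios: AreaRatios) -> float:
    """Composite area r_S * r_V / r_A — the structural correlate of
    elimination rate (large tSC and vacancy shares, small axon share).

    Undefined (raises) when ``r_A`` is zero.
    """
    if ratios.r_A <= 0:
        raise ValueError("composite area is undefined for r_A = 0")
    return ratios.r_S * ratios.r_V / ratios.r_A


@dataclass(frozen=True)
class RatioProfile:
    """A labelled composition, e.g. one endplate or one developmental stage."""

    label: str
    ratios: AreaRatios

    @property
    def composite_area(self) -> float:
        return composite_area(self.ratios)


@dataclass
class ExperimentSummary:
    """Batch statistics over the replicates of one condition.

    ``mean_iterations`` / ``sd_iterations`` are computed over completed runs
    (sample SD, ddof=1; ``None`` when fewer than two runs completed).  The
    ``win_table`` gives each winner's fraction of *all* replicates, so its
    values sum to ``completion_rate``.
    """

    label: str
    n_reps: int
    mean_iterations: float | None
    sd_iterations: float | None
    completion_rate: float
    win_table: dict[int | str, float]
    results: list[SimulationResult] = field(repr=False, default_factory=list)

    @classmethod
    def from_results(
        cls, label: str, results: Sequence[SimulationResult]
    ) -> "ExperimentSummary":
        n = len(results)
        completed = [r for r in results if r.completed]
        iters = np.array([r.iterations for r in completed], dtype=float)
        mean = float(iters.mean()) if len(iters) else None
        sd = float(iters.std(ddof=1)) if len(iters) > 1 else None
        win_table: dict[int | str, float] = {}
        for r in completed:
            win_table[r.winner] = win_table.get(r.winner, 0.0) + 1.0 / n
        return cls(
            label=label,
            n_reps=n,
            mean_iterations=mean,
            sd_iterations=sd,
            completion_rate=len(completed) / n,
            win_table=win_table,
            results=list(results),
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_reps": self.n_reps,
            "mean_iterations": self.mean_iterations,
            "sd_iterations": self.sd_iterations,
            "completion_rate": self.completion_rate,
            "win_table": {str(k): v for k, v in self.win_table.items()},
        }

    def iterations_sample(self) -> np.ndarray:
        """Least completion iterations of the completed replicates."""
        return np.array(
            [r.iterations for r in self.results if r.completed], dtype=float
        )


def _replicate_seeds(base_seed, n_reps: int) -> np.ndarray:
    """(n_reps, 3) integer seeds < 2**31: layout, run, activity streams."""
    ss = np.random.SeedSequence(base_seed)
    words = ss.generate_state(3 * n_reps, dtype=np.uint32)
    return (words.reshape(n_reps, 3) & 0x7FFFFFFF).astype(np.int64)


def _resolve_activity(
    config: RunConfig, act_seed: int
) -> ActivityConfig | None:
    act = config.activity
    if act.active_axon_ids:
        return ActivityConfig.of(act.active_axon_ids, act.selection_divisor)
    if act.n_active > 0:
        rng = np.random.default_rng(act_seed)
        ids = rng.choice(
            config.composition.n_axons, size=act.n_active, replace=False
        ) + 1
        return ActivityConfig.of(ids, act.selection_divisor)
    return None


def batch_run(
    config: RunConfig,
    n_reps: int | None = None,
    base_seed=None,
    record_series: bool = False,
    label: str | None = None,
    progress: bool = False,
) -> ExperimentSummary:
    """Run ``n_reps`` independent replicates of one condition.

    Each replicate gets a fresh random layout and fresh run streams, all
    derived deterministically from ``base_seed``; when the condition asks
    for ``n_active`` active axons the active set is redrawn per replicate.
    Incomplete runs (those reaching ``max_iter``) are retained and counted
    in ``completion_rate`` but excluded from the iteration statistics.
    """
    n_reps = config.execution.n_reps if n_reps is None else n_reps
    base_seed = config.execution.base_seed if base_seed is None else base_seed
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    probs = resolve_probs(config)
    seeds = _replicate_seeds(base_seed, n_reps)
    reps: Iterable[int] = range(n_reps)
    if progress:
        from tqdm import tqdm

        reps = tqdm(reps, desc=label or "batch", unit="run")
    results = []
    for rep in reps:
        layout_seed, run_seed, act_seed = (int(s) for s in seeds[rep])
        layout = build_layout(config, seed=layout_seed)
        activity = _resolve_activity(config, act_seed)
        result = run(
            layout,
            model=config.model.variant,
            probs=probs,
            activity=activity,
            max_iter=config.execution.max_iter,
            seed=run_seed,
            record_series=record_series,
            series_stride=config.execution.series_stride or 50,
        )
        results.append(result)
        logger.info(
            "rep %d: completed=%s iterations=%d winner=%s",
            rep,
            result.completed,
            result.iterations,
            result.winner,
        )
    return ExperimentSummary.from_results(label or config.model.variant, results)


@dataclass
class ActivityOutcome:
    """One activity condition: batch summary plus the active-set win rate."""

    n_active: int
    summary: ExperimentSummary
    active_win_fraction: float | None  # over completed runs; None if none completed


def activity_sweep(
    config: RunConfig,
    n_active_values: Sequence[int],
    n_reps: int | None = None,
    base_seed=None,
    progress: bool = False,
) -> dict[int, ActivityOutcome]:
    """Repeat the batch while varying how many axons are active.

    For each condition the active set is a fresh uniform draw per
    replicate.  The reported win fraction is the probability, over
    completed runs, that the winner belongs to the active set.
    """
    base_seed = config.execution.base_seed if base_seed is None else base_seed
    out: dict[int, ActivityOutcome] = {}
    for n_active in n_active_values:
        if not (0 <= n_active <= config.composition.n_axons):
            raise ValueError(f"n_active={n_active} outside 0..n_axons")
        cond = replace(
            config, activity=replace(config.activity, n_active=n_active)
        )
        summary = batch_run(
            cond,
            n_reps=n_reps,
            base_seed=(base_seed, n_active),
            label=f"active={n_active}",
            progress=progress,
        )
        completed = [r for r in summary.results if r.completed]
        if completed and n_active > 0:
            wins = sum(1 for r in completed if r.winner in r.active_axon_ids)
            frac = wins / len(completed)
        elif completed:
            frac = None
        else:
            frac = None
        out[n_active] = ActivityOutcome(n_active, summary, frac)
    return out


@dataclass
class RatioSweepResult:
    """Per-profile summaries plus the composite-area correlation."""

    summaries: dict[str, ExperimentSummary]
    composite_areas: dict[str, float]
    spearman_rho: float | None
    spearman_p: float | None
    skipped: list[str] = field(default_factory=list)


def ratio_sweep(
    profiles: Sequence[RatioProfile],
    config: RunConfig,
    n_reps: int | None = None,
    base_seed=None,
    runner: Callable[..., ExperimentSummary] | None = None,
    progress: bool = False,
) -> RatioSweepResult:
    """Batch each composition profile and correlate elimination time with
    composite area.

    The transition probabilities are re-solved per profile at the
    configured ``p_VS``; infeasible profiles are skipped with a warning.
    The two-tailed Spearman rank correlation relates each profile's
    composite area to its mean least completion iteration (``None`` when
    the ranks are degenerate, e.g. identical profiles).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a rank correlation")
    base_seed = config.execution.base_seed if base_seed is None else base_seed
    runner = batch_run if runner is None else runner
    summaries: dict[str, ExperimentSummary] = {}
    areas: dict[str, float] = {}
    skipped: list[str] = []
    for k, profile in enumerate(profiles):
        try:
            solve_stationary_probabilities(profile.ratios, config.model.p_vs)
        except (InfeasibleRatiosError, ValueError) as exc:
            logger.warning("skipping profile %s: %s", profile.label, exc)
            skipped.append(profile.label)
            continue
        cond = replace(
            config, model=replace(config.model, target_ratios=profile.ratios.as_tuple())
        )
        summaries[profile.label] = runner(
            cond,
            n_reps=n_reps,
            base_seed=(base_seed, k),
            label=profile.label,
            progress=progress,
        )
        areas[profile.label] = profile.composite_area
    labels = [
        lab for lab in summaries if summaries[lab].mean_iterations is not None
    ]
    rho = pval = None
    if len(labels) >= 3:
        x = np.array([areas[lab] for lab in labels])
        y = np.array([summaries[lab].mean_iterations for lab in labels])
        if np.unique(x).size > 1 and np.unique(y).size > 1:
            res = stats.spearmanr(x, y, alternative="two-sided")
            rho, pval = float(res.statistic), float(res.pvalue)
    return RatioSweepResult(
        summaries=summaries,
        composite_areas=areas,
        spearman_rho=rho,
        spearman_p=pval,
        skipped=skipped,
    )


@dataclass
class StageComparisonResult:
    """Per-stage summaries plus pairwise two-tailed t-tests."""

    summaries: dict[str, ExperimentSummary]
    ttests: dict[tuple[str, str], tuple[float, float]]  # (t, p)


def stage_comparison(
    stages: Sequence[str],
    config: RunConfig,
    n_reps: int | None = None,
    base_seed=None,
    equal_var: bool = False,
    progress: bool = False,
) -> StageComparisonResult:
    """Compare elimination times across developmental stages.

    For each stage the transition probabilities are solved from that
    stage's mean composition (Table-stage fixtures); initial layouts keep
    the configured (newborn) composition.  Pairwise two-tailed t-tests are
    run on the per-replicate least completion iterations (Welch by
    default; set ``equal_var=True`` for the pooled-variance form).
    """
    base_seed = config.execution.base_seed if base_seed is None else base_seed
    summaries: dict[str, ExperimentSummary] = {}
    for stage in stages:
        if stage not in STAGE_RATIOS:
            raise KeyError(f"unknown stage {stage!r}; have {sorted(STAGE_RATIOS)}")
        cond = replace(
            config,
            model=replace(
                config.model, target_ratios=STAGE_RATIOS[stage].as_tuple()
            ),
        )
        summaries[stage] = batch_run(
            cond,
            n_reps=n_reps,
            base_seed=(base_seed, list(STAGE_RATIOS).index(stage)),
            label=stage,
            progress=progress,
        )
    ttests: dict[tuple[str, str], tuple[float, float]] = {}
    names = list(summaries)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            xa = summaries[a].iterations_sample()
            xb = summaries[b].iterations_sample()
            res = stats.ttest_ind(xa, xb, equal_var=equal_var)
            ttests[(a, b)] = (float(res.statistic), float(res.pvalue))
    return StageComparisonResult(summaries=summaries, ttests=ttests)


def generate_ratio_variants(
    mean_ratios: AreaRatios,
    concentration: float = 50.0,
    n_profiles: int = 8,
    seed=None,
    p_vs: float = 0.6,
    max_attempts: int = 1000,
) -> list[RatioProfile]:
    """Synthetic per-endplate composition profiles around a mean.

    Emulates endplate-to-endplate variability by drawing compositions from
    a Dirichlet distribution with the given mean and concentration (larger
    concentration, tighter spread).  Draws that cannot be stabilised at the
    configured ``p_vs`` are rejected and redrawn, so every returned profile
    is feasible.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = mean_ratios.as_array() * concentration
    profiles: list[RatioProfile] = []
    attempts = 0
    while len(profiles) < n_profiles:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {n_profiles} feasible profiles in "
                f"{max_attempts} attempts; increase the concentration"
            )
        attempts += 1
        draw = rng.dirichlet(alpha)
        try:
            ratios = AreaRatios(float(draw[0]), float(draw[1]), float(draw[2]))
            solve_stationary_probabilities(ratios, p_vs)
        except (InfeasibleRatiosError, ValueError):
            continue
        profiles.append(
            RatioProfile(label=f"variant-{len(profiles) + 1:02d}", ratios=ratios)
        )
    return profiles
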