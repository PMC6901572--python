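"""Transition-probability structures and the stationary-ratio solver.

Two chains are supported on the three occupant classes, ordered
(tSC, vacancy, axon) throughout:

* a *general* chain in which every class may transition into every other
  (six independent probabilities, rows summing to one), and
* a *vacancy-mediated* chain in which axons and tSCs never convert into
  each other directly — every exchange of territory passes through a
  vacancy.  Its row structure is::

        tSC:      P_SS = 1 - P_SV,   P_SV,            0
        vacancy:  P_VS,              0,               P_VA = 1 - P_VS
        axon:     0,                 P_AV,            P_AA = 1 - P_AV

The vacancy-mediated chain has three independent probabilities
(P_AV, P_SV, P_VS).  Requiring a target composition vector r to be
stationary (r M = r) fixes two of them in terms of the third, which is
taken to be P_VS:

    P_SV = r_V * P_VS / r_S          P_AV = r_V * (1 - P_VS) / r_A

so the measured stage compositions determine the dynamics up to one free
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AreaRatios, SiteKind

__all__ = [
    "GeneralProbs",
    "VacancyMediatedProbs",
    "InfeasibleRatiosError",
    "DegenerateChainError",
    "DEFAULT_P_VS",
    "solve_stationary_probabilities",
    "stationary_vector",
    "sample_random_probs",
    "equal_probs",
]

#: Default free parameter P_VS; keeps every Table-stage composition feasible.
DEFAULT_P_VS = 0.6


class InfeasibleRatiosError(ValueError):
    """A derived transition probability fell outside [0, 1]."""


class DegenerateChainError(ValueError):
    """The chain is reducible, so its stationary distribution is not unique."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class GeneralProbs:
    """Six independent transition probabilities of the general scheme.

    Complements (the no-transition probabilities) are derived:
    ``p_AA = 1 - p_AV - p_AS`` and so on; each must itself lie in [0, 1],
    i.e. every row of the transition matrix is a probability vector.
    """

    p_AV: float
    p_AS: float
    p_SA: float
    p_SV: float
    p_VA: float
    p_VS: float

    def __post_init__(self) -> None:
        for name in ("p_AV", "p_AS", "p_SA", "p_SV", "p_VA", "p_VS"):
            _check_prob(name, getattr(self, name))
        for name in ("p_AA", "p_SS", "p_VV"):
            _check_prob(name, getattr(self, name))

    @property
    def p_AA(self) -> float:
        return 1.0 - self.p_AV - self.p_AS

    @property
    def p_SS(self) -> float:
        return 1.0 - self.p_SA - self.p_SV

    @property
    def p_VV(self) -> float:
        return 1.0 - self.p_VA - self.p_VS

    def row(self, kind: SiteKind) -> np.ndarray:
        """Outcome distribution for a site of ``kind``, ordered (S, V, A)."""
        if kind is SiteKind.TSC:
            return np.array([self.p_SS, self.p_SV, self.p_SA])
        if kind is SiteKind.VACANCY:
            return np.array([self.p_VS, self.p_VV, self.p_VA])
        return np.array([self.p_AS, self.p_AV, self.p_AA])

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 3x3 matrix over states ordered (S, V, A)."""
        return np.vstack(
            [self.row(SiteKind.TSC), self.row(SiteKind.VACANCY), self.row(SiteKind.AXON)]
        )


@dataclass(frozen=True)
class VacancyMediatedProbs:
    """The three independent probabilities of the vacancy-mediated scheme.

    Direct axon<->tSC transitions are structurally absent: ``p_AS`` and
    ``p_SA`` are zero by construction, and the complements are
    ``p_AA = 1 - p_AV``, ``p_SS = 1 - p_SV``, ``p_VA = 1 - p_VS``.
    """

    p_AV: float
    p_SV: float
    p_VS: float

    def __post_init__(self) -> None:
        for name in ("p_AV", "p_SV", "p_VS"):
            _check_prob(name, getattr(self, name))

    @property
    def p_AA(self) -> float:
        return 1.0 - self.p_AV

    @property
    def p_SS(self) -> float:
        return 1.0 - self.p_SV

    @property
    def p_VA(self) -> float:
        return 1.0 - self.p_VS

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 3x3 matrix over states ordered (S, V, A)."""
        return np.array(
            [
                [self.p_SS, self.p_SV, 0.0],
                [self.p_VS, 0.0, self.p_VA],
                [0.0, self.p_AV, self.p_AA],
            ]
        )

    def as_general(self) -> GeneralProbs:
        return GeneralProbs(
            p_AV=self.p_AV,
            p_AS=0.0,
            p_SA=0.0,
            p_SV=self.p_SV,
            p_VA=self.p_VA,
            p_VS=self.p_VS,
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "p_AV": self.p_AV,
            "p_SV": self.p_SV,
            "p_VS": self.p_VS,
            "p_AA": self.p_AA,
            "p_SS": self.p_SS,
            "p_VA": self.p_VA,
        }


def solve_stationary_probabilities(
    ratios: AreaRatios, p_VS: float = DEFAULT_P_VS
) -> VacancyMediatedProbs:
    """Solve the vacancy-mediated probabilities that hold ``ratios`` stationary.

    Given the free parameter ``p_VS``, the stationarity balance r M = r has
    the unique solution ``p_SV = r_V * p_VS / r_S`` and
    ``p_AV = r_V * (1 - p_VS) / r_A``.

    Raises
    ------
    InfeasibleRatiosError
        If a derived probability falls outside [0, 1] — the analogue of a
        composition that cannot be stabilised at this ``p_VS``.
    ValueError
        If ``r_S`` or ``r_A`` is zero (the solution is undetermined).
    """
    _check_prob("p_VS", p_VS)
    if ratios.r_S <= 0 or ratios.r_A <= 0:
        raise ValueError(
            "stationary probabilities are undetermined when r_S or r_A is 0"
        )
    p_sv = ratios.r_V * p_VS / ratios.r_S
    p_av = ratios.r_V * (1.0 - p_VS) / ratios.r_A
    # absorb division round-off exactly on the feasibility boundary
    if 1.0 < p_sv <= 1.0 + 1e-12:
        p_sv = 1.0
    if 1.0 < p_av <= 1.0 + 1e-12:
        p_av = 1.0
    if p_sv > 1.0:
        raise InfeasibleRatiosError(
            f"implied p_SV = r_V*p_VS/r_S = {p_sv:.6g} > 1 for ratios "
            f"{ratios.as_tuple()} at p_VS={p_VS}"
        )
    if p_av > 1.0:
        raise InfeasibleRatiosError(
            f"implied p_AV = r_V*(1-p_VS)/r_A = {p_av:.6g} > 1 for ratios "
            f"{ratios.as_tuple()} at p_VS={p_VS}"
        )
    return VacancyMediatedProbs(p_AV=p_av, p_SV=p_sv, p_VS=p_VS)


def _is_irreducible(M: np.ndarray) -> bool:
    # entries below 1e-8 are treated as absent edges: with a spectral gap
    # that small no floating-point route resolves the stationary vector to
    # the accuracy the rest of the package asserts, and every physically
    # meaningful transition probability is orders of magnitude larger
    reach = (M > 1e-8).astype(int)
    closure = reach + reach @ reach + reach @ reach @ reach
    return bool(np.all(closure > 0))


def stationary_vector(
    probs: VacancyMediatedProbs | GeneralProbs, tol: float = 1e-12
) -> AreaRatios:
    """Unique stationary distribution of a transition structure.

    Solves the balance equations ``pi M = pi, sum(pi) = 1`` by a linear
    solve, and cross-checks the answer with damped power iteration on
    ``(I + M) / 2`` (which shares the stationary vector but is always
    aperiodic).  The two routes must agree to ``1e-10``.

    Raises
    ------
    DegenerateChainError
        If the chain is reducible and the stationary vector not unique.
    """
    M = probs.transition_matrix()
    if not _is_irreducible(M):
        raise DegenerateChainError(
            "chain is reducible; stationary distribution is not unique"
        )
    A = np.vstack([M.T - np.eye(3), np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)

    # independent cross-check: power iteration by repeated squaring of the
    # damped kernel (I + M)/2 — aperiodic, same stationary vector, and the
    # squaring doubles the effective exponent each step, so convergence does
    # not depend on the spectral gap
    D = 0.5 * (np.eye(3) + M)
    for _ in range(200):
        D = D @ D
        D /= D.sum(axis=1, keepdims=True)
        if np.max(D.max(axis=0) - D.min(axis=0)) < tol:
            break
    v = D.mean(axis=0)
    if np.max(np.abs(v - pi)) > 5e-9:
        raise RuntimeError(
            f"stationary solvers disagree: linear {pi}, power iteration {v}"
        )
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return AreaRatios(float(pi[0]), float(pi[1]), float(pi[2]))


def sample_random_probs(rng: np.random.Generator) -> GeneralProbs:
    """Draw a fully random transition structure.

    Each row triple — e.g. (p_AA, p_AV, p_AS) — is uniform on the
    2-simplex (Dirichlet(1, 1, 1)), so every probability ranges over
    [0, 1] while each row still sums to one.
    """
    row_s = rng.dirichlet((1.0, 1.0, 1.0))  # (p_SS, p_SV, p_SA)
    row_v = rng.dirichlet((1.0, 1.0, 1.0))  # (p_VS, p_VV, p_VA)
    row_a = rng.dirichlet((1.0, 1.0, 1.0))  # (p_AS, p_AV, p_AA)
    return GeneralProbs(
        p_AV=float(row_a[1]),
        p_AS=float(row_a[0]),
        p_SA=float(row_s[2]),
        p_SV=float(row_s[1]),
        p_VA=float(row_v[2]),
        p_VS=float(row_v[0]),
    )


def equal_probs() -> GeneralProbs:
    """The general structure with every transition probability equal to 1/3."""
    third = 1.0 / 3.0
    return GeneralProbs(
        p_AV=third, p_AS=third, p_SA=third, p_SV=third, p_VA=third, p_VS=third
    )
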