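"""Hierarchical beta-binomial model for lost-to-follow-up outcomes.

The model treats each trial arm independently.  For an arm with ``n_o``
observed patients, ``X_o`` observed events and ``n_l`` patients lost to
follow up (LTFU):

* ``X_o | p_o ~ Binomial(n_o, p_o)`` with Jeffreys prior
  ``p_o ~ Beta(1/2, 1/2)``;
* the lost-patient incidence is dispersed around the observed one,
  ``p_l | p_o ~ Beta(s*p_o + 1, s - s*p_o + 1)``, whose mode is ``p_o``;
* ``X_l | p_l ~ Binomial(n_l, p_l)``.

The dispersion hyperparameter ``s`` interpolates between missing at
random (``s -> inf``, where ``p_l = p_o``) and a strong not-missing-at-
random assumption (``s = 0``, where ``p_l`` is uniform and independent of
``p_o``).  By default ``s`` is chosen so that a 75% equal-tail interval
of the ``p_l | p_o`` prior, evaluated at the plug-in sample proportion,
has right endpoint 1.3 times the sample proportion.

The quantity everything downstream consumes is the posterior predictive
distribution of the lost event count, ``X_l | X_o``, per arm and its
between-arm product over the joint grid of lost-outcome pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ArmObservation",
    "TrialTable",
    "PriorSettings",
    "PredictivePMF",
    "JointPredictive",
    "solve_s",
    "posterior_predictive_pmf",
    "joint_predictive",
    "impute_modes",
]

#: number of Gauss-Legendre nodes used for the quadrature method
QUADRATURE_NODES = 501

#: relative tolerance under which two probability masses count as tied modes
MODE_TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ArmObservation:
    """Summary counts for one trial arm.

    Parameters
    ----------
    events_observed:
        Number of observed patients with the event (``X_o``).
    nonevents_observed:
        Number of observed patients without the event (``n_o - X_o``).
    n_lost:
        Number of patients lost to follow up (``n_l``).
    label:
        Free-text arm name used in reports.
    """

    events_observed: int
    nonevents_observed: int
    n_lost: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("events_observed", "nonevents_observed", "n_lost"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.events_observed + self.nonevents_observed < 1:
            raise ValueError("at least one observed patient is required per arm")

    @property
    def n_observed(self) -> int:
        """Number of observed patients ``n_o``."""
        return self.events_observed + self.nonevents_observed

    @property
    def p_hat(self) -> float:
        """Observed incidence ``X_o / n_o``."""
        return self.events_observed / self.n_observed


@dataclass(frozen=True)
class TrialTable:
    """A two-arm trial summary; the arms are modelled independently."""

    control: ArmObservation
    treatment: ArmObservation


@dataclass(frozen=True)
class PriorSettings:
    """Hyperparameters of the lost-incidence prior and its default rule.

    ``s_control`` / ``s_treatment`` override the default rule when set;
    otherwise each arm's ``s`` is solved from its observed incidence so
    that the ``interval_mass`` equal-tail interval of
    ``Beta(s*p + 1, s - s*p + 1)`` has right endpoint ``multiplier * p``.
    """

    interval_mass: float = 0.75
    multiplier: float = 1.3
    s_control: float | None = None
    s_treatment: float | None = None
    jeffreys_a: float = 0.5
    jeffreys_b: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.interval_mass < 1.0:
            raise ValueError("interval_mass must lie strictly between 0 and 1")
        if self.multiplier <= 1.0:
            raise ValueError("multiplier must exceed 1")

    def resolve(self, trial: TrialTable) -> tuple[float, float]:
        """Return ``(s_control, s_treatment)``, solving the default rule where unset."""
        s_c = self.s_control
        s_t = self.s_treatment
        if s_c is None:
            s_c = solve_s(trial.control.p_hat, self.multiplier, self.interval_mass)
        if s_t is None:
            s_t = solve_s(trial.treatment.p_hat, self.multiplier, self.interval_mass)
        return float(s_c), float(s_t)


@dataclass(frozen=True)
class PredictivePMF:
    """Posterior predictive pmf of one arm's lost event count ``X_l | X_o``."""

    arm_label: str
    mass: np.ndarray
    method: str
    n_samples: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", mass)
        if mass.ndim != 1 or mass.size < 1:
            raise ValueError("mass must be a non-empty 1-D vector")
        if np.any(mass < 0):
            raise ValueError("probability masses must be non-negative")

    @property
    def n_lost(self) -> int:
        return self.mass.size - 1


@dataclass(frozen=True)
class JointPredictive:
    """Joint pmf over lost-event pairs ``(k_control, k_treatment)``.

    Stored as the outer product of the two arms' marginal predictive
    pmfs; rows index the control count, columns the treatment count.
    """

    mass: np.ndarray

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", mass)
        if mass.ndim != 2:
            raise ValueError("joint mass must be a 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mass.shape


def _right_endpoint(s: float, p_hat: float, interval_mass: float) -> float:
    """Upper equal-tail quantile of ``Beta(s*p + 1, s - s*p + 1)``."""
    upper = 0.5 * (1.0 + interval_mass)
    return float(stats.beta.ppf(upper, s * p_hat + 1.0, s * (1.0 - p_hat) + 1.0))


def solve_s(p_hat: float, multiplier: float = 1.3, interval_mass: float = 0.75) -> float:
    """Solve the default dispersion rule for ``s``.

    Finds ``s > 0`` such that the ``(1 + interval_mass)/2`` quantile of
    ``Beta(s*p_hat + 1, s - s*p_hat + 1)`` equals ``multiplier * p_hat``.
    The quantile decreases monotonically from the uniform quantile at
    ``s = 0`` towards ``p_hat`` as ``s`` grows, so a bracketing root
    search applies: the upper bracket is doubled from 1 until the
    quantile falls below the target, then Brent's method refines.

    Raises
    ------
    ValueError
        If ``multiplier * p_hat >= 1`` or the target endpoint is not
        reachable for any ``s >= 0`` (target outside the open interval
        ``(p_hat, uniform quantile)``).
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError("p_hat must lie strictly between 0 and 1")
    target = multiplier * p_hat
    if target >= 1.0:
        raise ValueError(f"multiplier*p_hat = {target:.4g} >= 1: no prior can satisfy the rule")
    uniform_quantile = 0.5 * (1.0 + interval_mass)
    if target >= uniform_quantile:
        raise ValueError(
            f"target endpoint {target:.4g} is not below the s=0 quantile "
            f"{uniform_quantile:.4g}; the rule has no root"
        )
    if target <= p_hat:
        raise ValueError("multiplier must exceed 1 for the rule to have a root")

    def objective(s: float) -> float:
        return _right_endpoint(s, p_hat, interval_mass) - target

    lo, hi = 1e-6, 1.0
    f_hi = objective(hi)
    while f_hi > 0.0:
        lo, hi = hi, hi * 2.0
        if hi > 1e12:  # pragma: no cover - guarded by the reachability checks above
            raise ValueError("no root found below s = 1e12")
        f_hi = objective(hi)
    root = optimize.brentq(objective, lo, hi, xtol=1e-9, rtol=1e-12)
    return float(root)


def _gauss_legendre_unit(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * (nodes + 1.0), 0.5 * weights


def _quadrature_pmf(arm: ArmObservation, s: float, n_nodes: int = QUADRATURE_NODES) -> np.ndarray:
    """Deterministic pmf of ``X_l | X_o`` by quadrature over ``p_o``.

    The integral over the Jeffreys posterior ``Beta(X_o + 1/2,
    n_o - X_o + 1/2)`` is evaluated in the probability-integral-transform
    variable ``u`` with ``p_o = F^{-1}(u)``, which absorbs the integrable
    endpoint singularities of the posterior density when ``X_o = 0`` or
    ``X_o = n_o`` and leaves a smooth integrand for Gauss-Legendre.
    """
    a = arm.events_observed + 0.5
    b = arm.nonevents_observed + 0.5
    u, w = _gauss_legendre_unit(n_nodes)
    p = stats.beta.ppf(u, a, b)
    k = np.arange(arm.n_lost + 1)
    # (n_l + 1, n_nodes) matrix of conditional beta-binomial masses
    cond = stats.betabinom.pmf(
        k[:, None], arm.n_lost, s * p[None, :] + 1.0, s * (1.0 - p[None, :]) + 1.0
    )
    return cond @ w


def _monte_carlo_pmf(
    arm: ArmObservation, s: float, n_samples: int, seed: int
) -> np.ndarray:
    """Empirical pmf from the three-part sampling scheme."""
    rng = np.random.default_rng(seed)
    a = arm.events_observed + 0.5
    b = arm.nonevents_observed + 0.5
    p_o = rng.beta(a, b, size=n_samples)
    p_l = rng.beta(s * p_o + 1.0, s * (1.0 - p_o) + 1.0)
    x_l = rng.binomial(arm.n_lost, p_l)
    counts = np.bincount(x_l, minlength=arm.n_lost + 1)
    return counts / n_samples


def posterior_predictive_pmf(
    arm: ArmObservation,
    s: float,
    method: str = "quadrature",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> PredictivePMF:
    """Posterior predictive pmf of the lost event count for one arm.

    Parameters
    ----------
    arm:
        The arm's observed summary.
    s:
        Dispersion hyperparameter; ``math.inf`` and ``0`` dispatch to the
        closed forms (beta-binomial and discrete uniform respectively)
        rather than taking quadrature limits.
    method:
        ``"quadrature"`` (deterministic, default) or ``"monte_carlo"``
        (the three-part sampling scheme; requires an explicit seed).
    n_samples, seed:
        Monte-Carlo controls; ignored for quadrature.
    """
    if s < 0:
        raise ValueError("s must be non-negative")
    if math.isinf(s):
        mass = stats.betabinom.pmf(
            np.arange(arm.n_lost + 1),
            arm.n_lost,
            arm.events_observed + 0.5,
            arm.nonevents_observed + 0.5,
        )
        return PredictivePMF(arm.label, mass, "closed_form_s_inf")
    if s == 0:
        mass = np.full(arm.n_lost + 1, 1.0 / (arm.n_lost + 1))
        return PredictivePMF(arm.label, mass, "closed_form_s_zero")
    if method == "quadrature":
        return PredictivePMF(arm.label, _quadrature_pmf(arm, s), "quadrature")
    if method in ("monte_carlo", "mc"):
        if n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if seed is None:
            raise ValueError("Monte-Carlo sampling requires an explicit seed")
        mass = _monte_carlo_pmf(arm, s, n_samples, seed)
        return PredictivePMF(arm.label, mass, "monte_carlo", n_samples=n_samples, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def joint_predictive(control_pmf: PredictivePMF, treatment_pmf: PredictivePMF) -> JointPredictive:
    """Joint pmf over lost-outcome pairs under between-arm independence."""
    return JointPredictive(np.outer(control_pmf.mass, treatment_pmf.mass))


def impute_modes(
    joint: JointPredictive, tie_tolerance: float = MODE_TIE_TOLERANCE
) -> list[tuple[int, int]]:
    """All cells whose mass ties the maximum, in row-major order.

    Ties are relative: a cell counts as a mode when its mass is within
    ``tie_tolerance`` (relative) of the maximum, so exact analytic ties
    split only by quadrature round-off are still reported together.
    """
    mass = joint.mass
    top = float(mass.max())
    rows, cols = np.nonzero(mass >= top * (1.0 - tie_tolerance))
    return [(int(r), int(c)) for r, c in zip(rows, cols)]
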