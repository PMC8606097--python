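"""Highest-density regions and the LTFU-aware fragility index.

The LTFU-aware fragility index asks: how many lost patients would need
outcomes *different from their model-expected (imputed) outcomes* for
the trial's significance conclusion to reverse?  Candidate lost-outcome
configurations are restricted to a highest-density region (HDR) of the
joint posterior predictive, so only "sufficiently likely" scenarios
count; the threshold ``q`` controls how much predictive mass may be
discarded.  ``q = 0`` permits every configuration (a generalised
tipping-point search); larger ``q`` makes the index more conservative.

Modifying one lost patient's outcome moves the joint event-count pair by
exactly one unit in one coordinate, so the number of modifications from
the imputed mode ``m`` to a candidate cell ``y`` is the L1 distance
``|y_C - m_C| + |y_T - m_T|``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    JointPredictive,
    PriorSettings,
    TrialTable,
    impute_modes,
    joint_predictive,
    posterior_predictive_pmf,
)
from .significance import SignificanceGrid, significance_grid

__all__ = [
    "HDRegion",
    "FragilityReport",
    "hdr",
    "max_reversal_q",
    "reversal_probability",
    "minimal_coverage",
    "ltfu_fragility_index",
]

#: relative tolerance for mass ties on the HDR boundary
HDR_TIE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class HDRegion:
    """A (1-q) highest density region over the joint lost-outcome grid."""

    cells: list
    q: float
    attained_coverage: float

    def member_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for r, c in self.cells:
            mask[r, c] = True
        return mask


@dataclass(frozen=True)
class FragilityReport:
    """Result of the full fragility pipeline on one trial."""

    fi: float  # count, possibly half-integer (median over tied modes), or inf
    q: float
    modes: list
    per_mode_minima: list
    achieving_cells: list
    reversal_probability: float
    max_reversal_q: float | None
    imputed_p_value: float
    baseline_p_value: float
    baseline_significant: bool
    alpha: float
    s_control: float
    s_treatment: float
    method: str
    seed: int | None = None

    @property
    def infinite(self) -> bool:
        return math.isinf(self.fi)


def _descending_order(mass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat masses and their row-major-stable descending order."""
    flat = mass.ravel()
    order = np.argsort(-flat, kind="stable")
    return flat, order


def hdr(joint: JointPredictive, q: float) -> HDRegion:
    """Smallest set of cells with cumulative mass >= 1 - q.

    Cells are accumulated in strictly decreasing mass order; all cells
    whose mass ties (relative ``1e-12``) with the last included cell are
    also included, so the region may slightly over-cover but is
    deterministic and nested across ``q``.  ``q = 0`` yields the full
    support; ``q = 1`` degenerates to the mode set.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    flat, order = _descending_order(joint.mass)
    if q == 0.0:
        # full support: float round-off in the cumulative sum must not
        # drop far-tail cells
        rows, cols = np.nonzero(np.ones_like(joint.mass, dtype=bool))
        cells = [(int(r), int(c)) for r, c in zip(rows, cols)]
        return HDRegion(cells=cells, q=0.0, attained_coverage=float(flat.sum()))
    cum = np.cumsum(flat[order])
    target = min(1.0 - q, float(cum[-1]))
    idx = int(np.searchsorted(cum, target - 1e-12))
    cutoff = flat[order[idx]]
    member = flat >= cutoff * (1.0 - HDR_TIE_TOLERANCE)
    rows, cols = np.nonzero(member.reshape(joint.mass.shape))
    cells = [(int(r), int(c)) for r, c in zip(rows, cols)]
    return HDRegion(cells=cells, q=q, attained_coverage=float(flat[member].sum()))


def minimal_coverage(joint: JointPredictive, cell: tuple[int, int]) -> float:
    """Smallest attained HDR coverage whose region includes ``cell``.

    Equals the cumulative descending mass through the cell, including
    boundary ties — i.e. the total mass of all cells at least as
    probable as the queried one.
    """
    r, c = cell
    n_r, n_c = joint.shape
    if not (0 <= r < n_r and 0 <= c < n_c):
        raise ValueError(f"cell {cell} outside grid {joint.shape}")
    flat = joint.mass.ravel()
    m = joint.mass[r, c]
    return float(flat[flat >= m * (1.0 - HDR_TIE_TOLERANCE)].sum())


def reversal_probability(joint: JointPredictive, grid: SignificanceGrid) -> float:
    """Posterior predictive probability that the lost outcomes reverse
    the baseline significance conclusion."""
    if joint.shape != grid.shape:
        raise ValueError("joint and grid shapes differ")
    return float(joint.mass[grid.reverses].sum())


def max_reversal_q(joint: JointPredictive, grid: SignificanceGrid) -> float | None:
    """Largest ``q`` whose HDR still contains a reversing cell.

    For each reversing cell the threshold at which it drops out of the
    HDR is one minus its minimal coverage; the maximum over reversing
    cells is the largest ``q`` for which ``hdr(q)`` intersects the
    reversal set.  Returns ``None`` when no cell reverses.
    """
    if joint.shape != grid.shape:
        raise ValueError("joint and grid shapes differ")
    rev = grid.reverses
    if not rev.any():
        return None
    flat, order = _descending_order(joint.mass)
    cum = np.cumsum(flat[order])
    # minimal coverage per sorted position, tie-inclusive: extend each
    # run of tied masses to the run's last cumulative value
    coverage = cum.copy()
    i = len(flat) - 1
    while i > 0:
        if flat[order[i - 1]] <= flat[order[i]] / (1.0 - HDR_TIE_TOLERANCE):
            coverage[i - 1] = coverage[i]
        i -= 1
    rev_flat = rev.ravel()[order]
    return float((1.0 - coverage[rev_flat]).max())


def ltfu_fragility_index(
    trial: TrialTable,
    q: float = 0.0,
    settings: PriorSettings | None = None,
    alpha: float = 0.05,
    method: str = "quadrature",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> FragilityReport:
    """Run the full fragility pipeline on a two-arm trial summary.

    Steps: resolve the dispersion hyperparameters, build each arm's
    posterior predictive and their joint, impute the modal lost-outcome
    pair, test every augmented table, restrict to the ``(1-q)`` HDR, and
    minimise the number of outcome modifications from the imputation to
    a significance-reversing cell.  With several tied modes the search
    runs from each mode and the median of the per-mode minima is
    reported (possibly half-integer, not rounded).

    An empty candidate set yields ``fi = inf`` — reversal is impossible
    within the sufficiently-likely region; this is a valid result, not
    an error.
    """
    if settings is None:
        settings = PriorSettings()
    s_c, s_t = settings.resolve(trial)
    pmf_c = posterior_predictive_pmf(
        trial.control, s_c, method=method, n_samples=n_samples, seed=seed
    )
    mc_seed = None if seed is None else seed + 1
    pmf_t = posterior_predictive_pmf(
        trial.treatment, s_t, method=method, n_samples=n_samples, seed=mc_seed
    )
    joint = joint_predictive(pmf_c, pmf_t)
    modes = impute_modes(joint)
    grid = significance_grid(trial, alpha=alpha)
    region = hdr(joint, q)
    rev = grid.reverses
    candidates = [cell for cell in region.cells if rev[cell]]

    imputed_p = float(grid.p_value[modes[0]])
    rev_prob = reversal_probability(joint, grid)
    max_q = max_reversal_q(joint, grid)

    if not candidates:
        return FragilityReport(
            fi=math.inf,
            q=q,
            modes=modes,
            per_mode_minima=[],
            achieving_cells=[],
            reversal_probability=rev_prob,
            max_reversal_q=max_q,
            imputed_p_value=imputed_p,
            baseline_p_value=grid.baseline_p_value,
            baseline_significant=bool(grid.baseline_significant),
            alpha=alpha,
            s_control=s_c,
            s_treatment=s_t,
            method=pmf_c.method,
            seed=seed,
        )

    cand = np.asarray(candidates)
    minima: list[int] = []
    achievers: list[list[tuple[int, int]]] = []
    for m_c, m_t in modes:
        dist = np.abs(cand[:, 0] - m_c) + np.abs(cand[:, 1] - m_t)
        best = int(dist.min())
        minima.append(best)
        achievers.append([tuple(map(int, cell)) for cell in cand[dist == best]])

    fi = float(np.median(minima))
    if fi.is_integer():
        fi = int(fi)
    # achieving cells from the mode(s) whose minimum determines the median
    order = np.argsort(minima, kind="stable")
    n = len(minima)
    mid = [order[(n - 1) // 2], order[n // 2]] if n % 2 == 0 else [order[n // 2]]
    achieving: list[tuple[int, int]] = []
    for i in dict.fromkeys(int(j) for j in mid):
        for cell in achievers[i]:
            if cell not in achieving:
                achieving.append(cell)

    return FragilityReport(
        fi=fi,
        q=q,
        modes=modes,
        per_mode_minima=minima,
        achieving_cells=achieving,
        reversal_probability=rev_prob,
        max_reversal_q=max_q,
        imputed_p_value=imputed_p,
        baseline_p_value=grid.baseline_p_value,
        baseline_significant=bool(grid.baseline_significant),
        alpha=alpha,
        s_control=s_c,
        s_treatment=s_t,
        method=pmf_c.method,
        seed=seed,
    )
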