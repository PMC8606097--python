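"""Trial input, machine-readable fragility reports and grid exports."""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragility import FragilityReport, hdr
from .model import ArmObservation, JointPredictive, TrialTable
from .significance import SignificanceGrid

__all__ = ["read_trial", "write_report", "export_grid", "plot_grid"]

REQUIRED_COLUMNS = ("arm", "events", "nonevents", "ltfu")


def read_trial(path: str | Path, treatment: str | None = None) -> TrialTable:
    """Read a two-arm trial summary from CSV.

    The file must have the header ``arm,events,nonevents,ltfu`` and
    exactly two data rows.  By convention the first row is the control
    arm; passing ``treatment=<label>`` names the treatment arm instead.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(df) != 2:
        raise ValueError(f"{path}: expected exactly 2 arm rows, found {len(df)}")
    arms = []
    for i, row in df.iterrows():
        for col in ("events", "nonevents", "ltfu"):
            value = row[col]
            if pd.isna(value) or int(value) != value or int(value) < 0:
                raise ValueError(
                    f"{path}: row {i} ({row['arm']!r}): column {col!r} must be a "
                    f"non-negative integer, got {value!r}"
                )
        arms.append(
            ArmObservation(
                events_observed=int(row["events"]),
                nonevents_observed=int(row["nonevents"]),
                n_lost=int(row["ltfu"]),
                label=str(row["arm"]),
            )
        )
    if treatment is not None:
        labels = [a.label for a in arms]
        if treatment not in labels:
            raise ValueError(
                f"{path}: --treatment {treatment!r} matches no arm in {labels}"
            )
        if arms[0].label == treatment:
            arms = arms[::-1]
    return TrialTable(control=arms[0], treatment=arms[1])


def report_to_dict(report: FragilityReport) -> dict:
    """JSON-ready dictionary for a fragility report.

    An infinite index is encoded as ``fi = null`` with an explicit
    ``"infinite": true`` flag rather than a sentinel number.
    """
    return {
        "fi": None if math.isinf(report.fi) else report.fi,
        "infinite": bool(math.isinf(report.fi)),
        "q": report.q,
        "modes": [list(m) for m in report.modes],
        "per_mode_minima": list(report.per_mode_minima),
        "achieving_cells": [list(c) for c in report.achieving_cells],
        "reversal_probability": report.reversal_probability,
        "max_reversal_q": report.max_reversal_q,
        "imputed_p_value": report.imputed_p_value,
        "baseline_p_value": report.baseline_p_value,
        "baseline_significant": report.baseline_significant,
        "s_control": report.s_control,
        "s_treatment": report.s_treatment,
        "alpha": report.alpha,
        "method": report.method,
        "seed": report.seed,
    }


def write_report(report: FragilityReport, path: str | Path) -> None:
    """Serialise a fragility report to JSON at full precision."""
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
        fh.write("\n")


def export_grid(
    grid: SignificanceGrid,
    joint: JointPredictive,
    hdr_qs: Sequence[float] = (),
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Long-format export of the lost-outcome grid, one row per cell.

    Columns: ``k_control``, ``k_treatment``, ``pmf``, ``p_value``,
    ``significant``, ``risk_difference`` and one ``in_hdr_<q>`` flag per
    requested threshold.  Written as CSV when ``path`` is given.
    """
    if grid.shape != joint.shape:
        raise ValueError("grid and joint shapes differ")
    n_c, n_t = grid.shape
    k_c, k_t = np.meshgrid(np.arange(n_c), np.arange(n_t), indexing="ij")
    df = pd.DataFrame(
        {
            "k_control": k_c.ravel(),
            "k_treatment": k_t.ravel(),
            "pmf": joint.mass.ravel(),
            "p_value": grid.p_value.ravel(),
            "significant": grid.significant.ravel(),
            "risk_difference": grid.risk_difference.ravel(),
        }
    )
    for q in hdr_qs:
        mask = hdr(joint, q).member_mask(grid.shape)
        df[f"in_hdr_{q:g}"] = mask.ravel()
    if path is not None:
        df.to_csv(path, index=False)
    return df


def plot_grid(
    grid: SignificanceGrid,
    joint: JointPredictive,
    modes: Sequence[tuple[int, int]] = (),
    path: str | Path | None = None,
):
    """Tile map of the lost-outcome grid (optional; needs matplotlib).

    Tile colour encodes significance of the augmented table, border
    shade the posterior predictive mass, and the imputed mode(s) are
    outlined.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    n_c, n_t = grid.shape
    fig, ax = plt.subplots(figsize=(max(4, n_t * 0.12), max(3, n_c * 0.12)))
    norm = joint.mass / joint.mass.max()
    for r in range(n_c):
        for c in range(n_t):
            fill = "#d7301f" if grid.significant[r, c] else "#2b8cbe"
            edge = (0.4, 0.1, 0.5, float(norm[r, c]))
            ax.add_patch(
                patches.Rectangle(
                    (c - 0.5, r - 0.5), 1, 1, facecolor=fill, edgecolor=edge, lw=1.2
                )
            )
    for r, c in modes:
        ax.add_patch(
            patches.Rectangle(
                (c - 0.5, r - 0.5), 1, 1, facecolor="none", edgecolor="black", lw=1.8
            )
        )
    ax.set_xlim(-0.5, n_t - 0.5)
    ax.set_ylim(-0.5, n_c - 0.5)
    ax.set_xlabel("lost events, treatment arm")
    ax.set_ylabel("lost events, control arm")
    ax.set_title(f"augmented-table significance (alpha={grid.alpha:g})")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
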