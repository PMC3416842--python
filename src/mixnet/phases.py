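"""Phase-space classification: HC / WC / SG / TS regions and coexistence maps.

Each point (alpha, T) or (nu, alpha) of parameter space is assigned one
label per dynamics kind (AM or SPR) and model variant:

* HC -- highly correlated retrieval: the retrieval branch exists with
  |m| >= theta_HC (anti-pattern retrieval, m <= -theta_HC, counts: the
  specular copies are stored alongside the patterns).  HC wins whenever
  retrieval and spin-glass solutions coexist.
* WC -- weakly correlated (one-set AM only): retrieval-type solutions
  exist but with 0 < |m| < theta_WC; at theta_WC = 0.5 such a state has at
  most 75% of its neurons correct, so no useful recall.
* SG -- only spin-glass solutions (m = 0, frozen disorder) remain.
* TS -- only the trivial solution exists.

A retrieval overlap landing inside [theta_WC, theta_HC) is reported as an
explicit indeterminate outcome rather than silently binned, and per-cell
solver failures carry their own label instead of aborting a whole grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meanfield import (
    MeanFieldContext,
    alpha_hc_zero_temperature,
    capacity_zero_temperature,
    critical_alpha,
    retrieval_zero_temperature,
    solve_branch,
)

__all__ = [
    "RegionLabel",
    "Thresholds",
    "PhaseDiagram",
    "classify_point",
    "phase_diagram",
    "coexistence_map",
]


class RegionLabel(str, enum.Enum):
    HC = "HC"
    WC = "WC"
    SG = "SG"
    TS = "TS"
    INDETERMINATE = "IND"   # overlap inside [theta_WC, theta_HC)
    FAILED = "FAIL"         # solver failure at this cell


@dataclass(frozen=True)
class Thresholds:
    """Overlap cutoffs separating high from weak correlation."""

    theta_hc: float = 0.9
    theta_wc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wc <= self.theta_hc < 1.0:
            raise ValueError("need 0 < theta_WC <= theta_HC < 1")


@dataclass
class PhaseDiagram:
    """Region label per grid cell, plus the context that produced it."""

    alpha_grid: np.ndarray
    t_grid: np.ndarray
    labels: np.ndarray          # shape (len(alpha_grid), len(t_grid))
    dynamics: str
    variant: str
    nu: float
    thresholds: Thresholds

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"alpha": float(a), "temperature": float(t),
             "region": self.labels[i, j]}
            for i, a in enumerate(self.alpha_grid)
            for j, t in enumerate(self.t_grid)
        ]
        return pd.DataFrame(rows)


def _retrieval_overlap(ctx: MeanFieldContext):
    """|m| of the retrieval branch, None if absent, 'fail' on divergence."""
    if ctx.temperature == 0:
        m = retrieval_zero_temperature(ctx.dynamics, ctx.variant, ctx.nu, ctx.alpha)
        return None if m is None else abs(m)
    res = solve_branch(ctx, "retrieval")
    if res.status == "diverged":
        return "fail"
    if res.status == "no_solution":
        return None
    return abs(res.op.m)


def _sg_exists(ctx: MeanFieldContext):
    if ctx.temperature == 0:
        return True  # the zero-T spin-glass state exists for every alpha > 0, nu
    res = solve_branch(ctx, "spin_glass")
    if res.status == "diverged":
        return "fail"
    return res.converged


def classify_point(ctx: MeanFieldContext,
                   thresholds: Thresholds = Thresholds()) -> RegionLabel:
    """Assign one region label to a parameter-space point."""
    if ctx.alpha == 0:
        # zero load: pure mean-field ferromagnet in the condensed direction
        ctx = MeanFieldContext(1e-6, ctx.nu, ctx.temperature, ctx.dynamics, ctx.variant)
    m = _retrieval_overlap(ctx)
    if m == "fail":
        return RegionLabel.FAILED
    if m is not None:
        if m >= thresholds.theta_hc:
            return RegionLabel.HC
        if m >= thresholds.theta_wc:
            return RegionLabel.INDETERMINATE
        # weakly correlated band: a feature of the one-set AM system only;
        # elsewhere a sub-threshold condensed branch is not useful retrieval
        # and the point is classified by its disordered solutions
        if ctx.dynamics == "AM" and ctx.variant == "one_set":
            return RegionLabel.WC
    sg = _sg_exists(ctx)
    if sg == "fail":
        return RegionLabel.FAILED
    return RegionLabel.SG if sg else RegionLabel.TS


def phase_diagram(dynamics: str, variant: str, nu: float,
                  alpha_grid=None, t_grid=None,
                  thresholds: Thresholds = Thresholds()) -> PhaseDiagram:
    """Classify every cell of an (alpha, T) grid at fixed nu.

    Defaults bracket every phase boundary of interest: alpha in [0, 0.35],
    T in [0, 1.5].  Solver failures are labelled per cell, never raised.
    """
    alpha_grid = np.linspace(0.0, 0.35, 101) if alpha_grid is None else np.asarray(alpha_grid)
    t_grid = np.linspace(0.0, 1.5, 101) if t_grid is None else np.asarray(t_grid)
    if np.any(np.diff(alpha_grid) <= 0) or np.any(np.diff(t_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    labels = np.empty((alpha_grid.size, t_grid.size), dtype=object)
    for i, a in enumerate(alpha_grid):
        for j, t in enumerate(t_grid):
            try:
                ctx = MeanFieldContext(float(a), nu, float(t), dynamics, variant)
                labels[i, j] = classify_point(ctx, thresholds).value
            except Exception:
                labels[i, j] = RegionLabel.FAILED.value
    return PhaseDiagram(alpha_grid, t_grid, labels, dynamics, variant, nu, thresholds)


def _hc_boundary(dynamics: str, variant: str, nu: float, temperature: float,
                 thresholds: Thresholds) -> float:
    """Largest alpha with an HC-grade retrieval solution at (nu, T)."""
    if temperature == 0:
        return alpha_hc_zero_temperature(dynamics, variant, nu, thresholds.theta_hc)
    try:
        return critical_alpha(dynamics, variant, nu, temperature,
                              m_threshold=thresholds.theta_hc)
    except ValueError:
        return 0.0


def coexistence_map(variant: str, temperature: float, nu_grid=None,
                    alpha_grid=None,
                    thresholds: Thresholds = Thresholds()):
    """AM-HC and SPR-HC regions in the (nu, alpha) plane and their intersection.

    Returns ``(table, nonempty)`` where the table has one row per (nu,
    alpha) cell with boolean columns am_hc, spr_hc, both, and ``nonempty``
    says whether any cell supports both dynamics at once (coexistence).
    """
    nu_grid = np.linspace(0.0, 1.0, 41) if nu_grid is None else np.asarray(nu_grid)
    alpha_grid = np.linspace(0.0025, 0.3, 40) if alpha_grid is None else np.asarray(alpha_grid)
    am_limit = np.array([_hc_boundary("AM", variant, float(nu), temperature, thresholds)
                         for nu in nu_grid])
    spr_limit = np.array([_hc_boundary("SPR", variant, float(nu), temperature, thresholds)
                          for nu in nu_grid])
    rows = []
    nonempty = False
    for i, nu in enumerate(nu_grid):
        for a in alpha_grid:
            am_hc = bool(a <= am_limit[i])
            spr_hc = bool(a <= spr_limit[i])
            both = am_hc and spr_hc
            nonempty = nonempty or both
            rows.append({"nu": float(nu), "alpha": float(a),
                         "am_hc": am_hc, "spr_hc": spr_hc, "both": both})
    return pd.DataFrame(rows), nonempty
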