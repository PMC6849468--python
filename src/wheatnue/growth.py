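"""Broken-stick (split-line) growth analysis of biomass trajectories.

Shoot biomass of a wheat plant accumulates sigmoidally: a lag phase, a
near-linear phase of rapid growth, and a plateau towards maturity.  Within a
typical imaging window only one bend of the sigmoid is visible, so the series
of estimated biomass (EB, kilopixels) against days after sowing (DAS) is
modelled as two straight lines joined continuously at a breakpoint:

    y = a + b1 * x                    for x <= c
    y = a + b1 * c + b2 * (x - c)     for x >  c

For a fixed breakpoint ``c`` this model is linear in ``(a, b1, b2)`` and is
solved by ordinary least squares; the breakpoint itself is profiled on a
dense grid over the interior of the observed DAS range and refined locally.
If the second slope exceeds the first the breakpoint marks the *commencement*
of the linear phase, otherwise its *completion*; the interval from the latest
commencement to the earliest completion across varieties is the window in
which every variety grows linearly, the recommended time for single-day
vegetative screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "BrokenStickFit",
    "LinearPhaseWindow",
    "fit_broken_stick",
    "classify_phase",
    "common_linear_window",
    "recommend_screening_das",
    "fit_variety_means",
    "fits_from_table",
    "broken_stick_sse",
]

PHASE_COMMENCEMENT = "commencement"
PHASE_COMPLETION = "completion"
PHASE_AMBIGUOUS = "ambiguous"

#: relative slope difference below which the two segments are considered equal
SLOPE_TOL = 1e-6


@dataclass(frozen=True)
class BrokenStickFit:
    """Result of one split-line fit.

    ``breakpoint_x``/``breakpoint_y`` are the DAS/EB coordinates of the join
    point; ``slope1``/``slope2`` the segment slopes in kPix/day before and
    after it; ``adj_r2`` uses p = 4 estimated parameters (intercept, two
    slopes, breakpoint).
    """

    breakpoint_x: float
    breakpoint_y: float
    slope1: float
    slope2: float
    intercept: float
    adj_r2: float
    sse: float
    phase: str
    variety: str | None = None
    n_level: str | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        left = self.intercept + self.slope1 * x
        right = (
            self.intercept
            + self.slope1 * self.breakpoint_x
            + self.slope2 * (x - self.breakpoint_x)
        )
        return np.where(x <= self.breakpoint_x, left, right)


@dataclass(frozen=True)
class LinearPhaseWindow:
    """DAS interval in which all contributing varieties grow linearly."""

    n_level: str | None
    start_das: float
    end_das: float
    commencing_varieties: tuple[str, ...]
    completing_varieties: tuple[str, ...]

    @property
    def empty(self) -> bool:
        return self.start_das > self.end_das


def _solve_at_breakpoint(x: np.ndarray, y: np.ndarray, c: float):
    """OLS for fixed breakpoint; returns (a, b1, b2, sse)."""
    design = np.column_stack([np.ones_like(x), np.minimum(x, c), np.maximum(x - c, 0.0)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef[0], coef[1], coef[2], float(resid @ resid)


def broken_stick_sse(x: np.ndarray, y: np.ndarray, c: float) -> float:
    """Profile SSE of the continuous two-segment model at breakpoint ``c``."""
    return _solve_at_breakpoint(np.asarray(x, float), np.asarray(y, float), c)[3]


def fit_broken_stick(
    das: Sequence[float],
    eb: Sequence[float],
    *,
    grid_step: float = 0.1,
    variety: str | None = None,
    n_level: str | None = None,
) -> BrokenStickFit:
    """Fit the continuous two-segment regression to one growth series.

    The breakpoint is profiled on a grid of ``grid_step`` DAS over the
    interval from the second to the penultimate observation, then refined by
    bounded golden-section search in the bracket around the grid minimum.
    Ties on the grid break toward the earliest breakpoint.

    Requires at least 5 observations with strictly increasing DAS and
    non-negative EB.  An all-constant series yields the degenerate fit with
    both slopes zero and phase "ambiguous".
    """
    x = np.asarray(das, dtype=float)
    y = np.asarray(eb, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("das and eb must be one-dimensional and equally long")
    if len(x) < 5:
        raise ValueError(f"at least 5 observations are required, got {len(x)}")
    if not np.all(np.diff(x) > 0):
        raise ValueError("das must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("eb must be non-negative")

    if np.ptp(y) == 0.0:
        c = float(x[len(x) // 2])
        return BrokenStickFit(
            breakpoint_x=c,
            breakpoint_y=float(y[0]),
            slope1=0.0,
            slope2=0.0,
            intercept=float(y[0]),
            adj_r2=0.0,
            sse=0.0,
            phase=PHASE_AMBIGUOUS,
            variety=variety,
            n_level=n_level,
        )

    # profile on a centred axis: better conditioned and exactly shift-equivariant
    x0 = float(x[0])
    xc = x - x0
    lo, hi = float(xc[1]), float(xc[-2])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid = np.clip(grid, lo, hi)
    sses = np.array([broken_stick_sse(xc, y, c) for c in grid])
    best = int(np.argmin(sses))  # argmin takes the first minimum: earliest wins

    bracket_lo = grid[max(best - 1, 0)]
    bracket_hi = grid[min(best + 1, len(grid) - 1)]
    if bracket_hi > bracket_lo:
        res = minimize_scalar(
            lambda c: broken_stick_sse(xc, y, c),
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        c_hat = float(res.x) if res.fun <= sses[best] else float(grid[best])
    else:
        c_hat = float(grid[best])

    a, b1, b2, sse = _solve_at_breakpoint(xc, y, c_hat)
    c_hat = c_hat + x0
    a = a - b1 * x0  # intercept back on the original DAS axis
    n = len(x)
    sst = float(np.sum((y - y.mean()) ** 2))
    p = 4
    adj_r2 = 1.0 - (sse / max(n - p, 1)) / (sst / (n - 1)) if sst > 0 else 0.0
    fit = BrokenStickFit(
        breakpoint_x=c_hat,
        breakpoint_y=float(a + b1 * c_hat),
        slope1=float(b1),
        slope2=float(b2),
        intercept=float(a),
        adj_r2=float(adj_r2),
        sse=sse,
        phase="",
        variety=variety,
        n_level=n_level,
    )
    return BrokenStickFit(**{**fit.__dict__, "phase": classify_phase(fit)})


def classify_phase(fit: BrokenStickFit, tol: float = SLOPE_TOL) -> str:
    """Label a fit's breakpoint as linear-phase commencement or completion.

    A steeper second segment means growth accelerates at the breakpoint, so it
    marks the start of the linear phase; a flatter second segment means it
    marks the end.  Slopes equal within ``tol`` (relative to the larger
    magnitude) are ambiguous, as for an effectively straight series.
    """
    s1, s2 = fit.slope1, fit.slope2
    if not (np.isfinite(s1) and np.isfinite(s2)):
        raise ValueError("slopes must be finite")
    scale = max(abs(s1), abs(s2))
    if abs(s1 - s2) <= tol * scale or scale == 0.0:
        return PHASE_AMBIGUOUS
    return PHASE_COMMENCEMENT if s2 > s1 else PHASE_COMPLETION


def common_linear_window(
    fits: Iterable[BrokenStickFit],
    *,
    n_level: str | None = None,
    observed_range: tuple[float, float] | None = None,
) -> LinearPhaseWindow:
    """Window in which every variety is in its linear growth phase.

    The window starts at the latest commencement breakpoint (every variety has
    started) and ends at the earliest completion breakpoint (none has yet
    finished).  When no fit of one kind is present the corresponding bound
    falls back to the observed DAS range, which must then be supplied.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("at least one fit is required")
    commence = [f for f in fits if f.phase == PHASE_COMMENCEMENT]
    complete = [f for f in fits if f.phase == PHASE_COMPLETION]
    if not commence and not complete:
        raise ValueError(
            "all fits are ambiguous; inspect the series before deriving a window"
        )
    if (not commence or not complete) and observed_range is None:
        raise ValueError(
            "observed_range is required when commencement or completion fits are absent"
        )
    start = max(f.breakpoint_x for f in commence) if commence else observed_range[0]
    end = min(f.breakpoint_x for f in complete) if complete else observed_range[1]
    return LinearPhaseWindow(
        n_level=n_level,
        start_das=float(start),
        end_das=float(end),
        commencing_varieties=tuple(f.variety or "?" for f in commence),
        completing_varieties=tuple(f.variety or "?" for f in complete),
    )


def recommend_screening_das(
    window: LinearPhaseWindow, imaging_days: Sequence[float]
) -> float:
    """Pick the imaging day for single-day vegetative screening.

    Returns the imaging day inside the window closest to its midpoint; on an
    exact tie the later day wins (plants are larger, segmentation more
    reliable).
    """
    if window.empty:
        raise ValueError("the linear-phase window is empty")
    inside = [d for d in imaging_days if window.start_das <= d <= window.end_das]
    if not inside:
        raise ValueError(
            f"no imaging day falls inside the window "
            f"[{window.start_das}, {window.end_das}]"
        )
    mid = (window.start_das + window.end_das) / 2.0
    return float(max(inside, key=lambda d: (-abs(d - mid), d)))


def fit_variety_means(
    traits: pd.DataFrame,
    *,
    grid_step: float = 0.1,
    per_pot: bool = False,
) -> pd.DataFrame:
    """Fit the split-line model per variety x N level (or per pot).

    ``traits`` needs columns ``variety, n_level, das, eb_kpix`` (plus
    ``pot_id`` when ``per_pot``).  By default replicate pots are averaged per
    DAS first, giving one fit per variety as in a varietal screen report.
    Returns a tidy table with breakpoint coordinates, slopes, adjusted R² and
    phase.
    """
    required = {"variety", "n_level", "das", "eb_kpix"}
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"trait table is missing columns: {sorted(missing)}")
    keys = ["variety", "n_level"] + (["pot_id"] if per_pot else [])
    rows = []
    for key, group in traits.groupby(keys, sort=True):
        if not per_pot:
            series = group.groupby("das", sort=True)["eb_kpix"].mean().reset_index()
        else:
            series = group.sort_values("das")[["das", "eb_kpix"]]
        fit = fit_broken_stick(
            series["das"].to_numpy(),
            series["eb_kpix"].to_numpy(),
            grid_step=grid_step,
            variety=str(key[0]),
            n_level=str(key[1]),
        )
        row = {
            "variety": key[0],
            "n_level": key[1],
            "breakpoint_x": fit.breakpoint_x,
            "breakpoint_y": fit.breakpoint_y,
            "slope1": fit.slope1,
            "slope2": fit.slope2,
            "adj_r2": fit.adj_r2,
            "phase": fit.phase,
        }
        if per_pot:
            row["pot_id"] = key[2]
        rows.append(row)
    return pd.DataFrame(rows)


def fits_from_table(table: pd.DataFrame) -> list[BrokenStickFit]:
    """Build classified fits from a table of published or exported split-line
    parameters (columns ``variety, n_level, breakpoint_x, breakpoint_y,
    slope1, slope2``), e.g. to re-derive phase labels and windows without the
    underlying image series."""
    fits = []
    for rec in table.itertuples():
        fit = BrokenStickFit(
            breakpoint_x=float(rec.breakpoint_x),
            breakpoint_y=float(rec.breakpoint_y),
            slope1=float(rec.slope1),
            slope2=float(rec.slope2),
            intercept=float(rec.breakpoint_y) - float(rec.slope1) * float(rec.breakpoint_x),
            adj_r2=float("nan"),
            sse=float("nan"),
            phase="",
            variety=str(rec.variety),
            n_level=str(rec.n_level),
        )
        fits.append(BrokenStickFit(**{**fit.__dict__, "phase": classify_phase(fit)}))
    return fits
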