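"""Survival tables and 1/Y²-weighted least-squares decay fits.

A :class:`SurvivalTable` holds, for one day-0 cohort, the percentage of
spines still present at each imaging day.  Fitting minimizes the weighted sum
of squares Σ (Yᵢ − Ŷ(tᵢ))²/Yᵢ² — i.e. relative residuals — over the model
parameters.  Points with Yᵢ = 0 carry an undefined (infinite) weight and are
excluded.  Optimization uses bounded trust-region least squares with a small
deterministic multi-start to guard against local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    DecayModel,
    SinglePhaseDecay,
    TwoStageDecay,
    model_to_dict,
    survival,
)

__all__ = [
    "SurvivalTable",
    "DecayFit",
    "build_survival_table",
    "fit_single_phase",
    "fit_two_stage",
    "weighted_sse",
]

_TAU_BOUNDS = (0.05, 500.0)


@dataclass(frozen=True)
class SurvivalTable:
    """Observed surviving fractions of a day-0 cohort.

    ``days`` are relative to the cohort-definition day; the fraction there is
    100% by construction.
    """

    cohort_label: str
    days: np.ndarray
    n_surviving: np.ndarray
    n_initial: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))
        object.__setattr__(self, "n_surviving", np.asarray(self.n_surviving, dtype=int))
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")
        if len(self.days) != len(self.n_surviving):
            raise ValueError("days and n_surviving length mismatch")

    @property
    def fraction_percent(self) -> np.ndarray:
        return 100.0 * self.n_surviving / self.n_initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "n_surviving": self.n_surviving,
                "n_initial": self.n_initial,
                "fraction_percent": self.fraction_percent,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cohort_label: str = "") -> "SurvivalTable":
        df = pd.read_csv(path)
        return cls(
            cohort_label=cohort_label or Path(str(path)).stem,
            days=df["day"].to_numpy(),
            n_surviving=df["n_surviving"].to_numpy(),
            n_initial=int(df["n_initial"].iloc[0]),
        )


@dataclass(frozen=True)
class DecayFit:
    """A fitted decay model with its weighted objective value."""

    model: DecayModel
    weighted_sse: float
    n_points: int
    fixed_parameters: tuple = ()
    converged: bool = True

    def to_dict(self) -> dict:
        d = model_to_dict(self.model)
        d.update(
            weighted_sse=self.weighted_sse,
            n_points=self.n_points,
            fixed_parameters=list(self.fixed_parameters),
            converged=self.converged,
        )
        return d


def build_survival_table(
    table: pd.DataFrame,
    cohort: Union[str, Callable, Sequence, None] = None,
    *,
    cohort_day: int = 0,
    strict: bool = False,
    label: Optional[str] = None,
) -> SurvivalTable:
    """Count cohort spines surviving at each observation day >= ``cohort_day``.

    Parameters
    ----------
    table
        Long-format longitudinal table (see :mod:`spinesurvival.simulate`).
    cohort
        Which day-0 spines form the cohort: ``"sp_pos"`` / ``"sp_neg"``
        (present spines in that SP state), a callable mapping the day-0
        sub-frame to a boolean mask, an explicit sequence of spine ids, or
        ``None`` for all spines present at ``cohort_day``.
    strict
        If False (default), a spine absent at day t but present at any later
        day still counts as surviving at t (absence treated as a detection
        miss).  If True, the first absence counts as loss.
    """
    day0 = table[table["day"] == cohort_day]
    if day0.empty:
        raise ValueError(f"table has no rows at cohort day {cohort_day}")

    if cohort is None:
        mask = day0["present"].to_numpy(dtype=bool)
    elif isinstance(cohort, str):
        if cohort not in ("sp_pos", "sp_neg"):
            raise ValueError("cohort string must be 'sp_pos' or 'sp_neg'")
        want = cohort == "sp_pos"
        mask = (
            day0["present"].to_numpy(dtype=bool)
            & (day0["sp_positive"] == want).fillna(False).to_numpy(dtype=bool)
        )
    elif callable(cohort):
        mask = np.asarray(cohort(day0), dtype=bool)
        mask &= day0["present"].to_numpy(dtype=bool)
    else:
        ids = set(cohort)
        mask = day0["spine_id"].isin(ids).to_numpy() & day0["present"].to_numpy(
            dtype=bool
        )

    ids = day0.loc[mask, "spine_id"]
    if ids.empty:
        raise ValueError("cohort is empty at the cohort-definition day")

    sub = table[(table["spine_id"].isin(ids)) & (table["day"] >= cohort_day)]
    presence = (
        sub.pivot(index="spine_id", columns="day", values="present")
        .sort_index(axis=1)
        .to_numpy(dtype=bool)
    )
    days = np.sort(sub["day"].unique())
    if not strict:
        # surviving at day t <=> present at t or at any later day
        presence = np.logical_or.accumulate(presence[:, ::-1], axis=1)[:, ::-1]
    else:
        # first absence is terminal
        presence = np.logical_and.accumulate(presence, axis=1)
    n_surviving = presence.sum(axis=0)

    if isinstance(cohort, str) and label is None:
        label = cohort
    return SurvivalTable(
        cohort_label=label or "cohort",
        days=days.astype(float) - cohort_day,
        n_surviving=n_surviving,
        n_initial=int(len(ids)),
    )


def weighted_sse(model: DecayModel, days, fractions) -> float:
    """Σ (Y − Ŷ)²/Y² over points with Y > 0 (the fit objective)."""
    days = np.asarray(days, dtype=float)
    y = np.asarray(fractions, dtype=float)
    keep = y > 0
    yhat = survival(model, days[keep])
    return float(np.sum(((y[keep] - yhat) / y[keep]) ** 2))


def _usable_points(st: SurvivalTable):
    y = st.fraction_percent
    keep = y > 0
    return st.days[keep], y[keep]


def _crude_tau_init(t: np.ndarray, y: np.ndarray) -> float:
    """ln2-scaled crude half-life estimate from the observed fractions."""
    if y.min() < 50.0:
        # first crossing of 50% by linear interpolation on the decreasing tail
        order = np.argsort(t)
        t_s, y_s = t[order], y[order]
        idx = int(np.argmax(y_s < 50.0))
        if idx == 0:
            t_half = t_s[0] if t_s[0] > 0 else 1.0
        else:
            t0, t1 = t_s[idx - 1], t_s[idx]
            y0, y1 = y_s[idx - 1], y_s[idx]
            t_half = t0 + (y0 - 50.0) / (y0 - y1) * (t1 - t0)
        tau0 = t_half / math.log(2.0)
    else:
        y_last = y[np.argmax(t)]
        if y_last < 100.0:
            tau0 = -(t.max() - t.min()) / math.log(y_last / 100.0)
        else:
            tau0 = max(t.max() - t.min(), 1.0)
    return float(np.clip(tau0, *_TAU_BOUNDS))


def _default_offset_upper(t: np.ndarray, y: np.ndarray) -> float:
    """Decay must start no later than the first observed loss."""
    below = t[y < 100.0]
    return float(below.min()) if below.size else float(t.max())


def fit_single_phase(
    st: SurvivalTable,
    bounds: Optional[dict] = None,
    init: Optional[dict] = None,
) -> DecayFit:
    """Fit ``Y = 100·exp(−(t−offset)/τ)`` by 1/Y²-weighted least squares.

    ``bounds`` may override ``{"tau_spine": (lo, hi), "offset": (lo, hi)}``;
    ``init`` may override ``{"tau_spine": x, "offset": x}``.
    """
    t, y = _usable_points(st)
    if len(t) < 3:
        raise ValueError(f"need >= 3 points with fraction > 0, got {len(t)}")

    bounds = dict(bounds or {})
    tau_b = bounds.get("tau_spine", _TAU_BOUNDS)
    off_b = bounds.get("offset", (-1.0, _default_offset_upper(t, y)))
    init = dict(init or {})
    tau0 = float(init.get("tau_spine", _crude_tau_init(t, y)))
    off0 = float(np.clip(init.get("offset", 0.0), *off_b))

    def residuals(p):
        yhat = survival(SinglePhaseDecay(p[0], p[1]), t)
        return (y - yhat) / y

    lo = np.array([tau_b[0], off_b[0]])
    hi = np.array([tau_b[1], off_b[1]])
    starts = [
        np.clip(np.array([tau0, off0]), lo, hi),
        np.clip(np.array([tau0 / 2.0, off_b[0]]), lo, hi),
        np.clip(np.array([tau0 * 2.0, (off_b[0] + off_b[1]) / 2.0]), lo, hi),
    ]
    best = None
    ok = False
    for p0 in starts:
        res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        if best is None or res.cost < best.cost:
            best, ok = res, bool(res.success)
    model = SinglePhaseDecay(float(best.x[0]), float(best.x[1]))
    return DecayFit(
        model=model,
        weighted_sse=float(2.0 * best.cost),
        n_points=len(t),
        fixed_parameters=(),
        converged=ok,
    )


def fit_two_stage(
    st: SurvivalTable,
    tau_spine_fixed: Optional[float] = None,
    *,
    fit_tau_spine: bool = False,
    bounds: Optional[dict] = None,
) -> DecayFit:
    """Fit the two-stage model's τ_SP with τ_spine held fixed.

    τ_spine is normally pinned to the companion SP⁻ cohort's single-phase fit
    (pass it as ``tau_spine_fixed``); set ``fit_tau_spine=True`` to co-fit
    both constants instead.
    """
    t, y = _usable_points(st)
    min_pts = 3 if fit_tau_spine else 2
    if len(t) < min_pts:
        raise ValueError(f"need >= {min_pts} points with fraction > 0, got {len(t)}")
    if not fit_tau_spine:
        if tau_spine_fixed is None or not tau_spine_fixed > 0:
            raise ValueError("tau_spine_fixed must be a positive number")

    bounds = dict(bounds or {})
    tau_b = bounds.get("tau_sp", _TAU_BOUNDS)
    tau_spine_b = bounds.get("tau_spine", _TAU_BOUNDS)

    if fit_tau_spine:

        def residuals(p):
            return (y - survival(TwoStageDecay(p[0], p[1]), t)) / y

        lo = np.array([tau_b[0], tau_spine_b[0]])
        hi = np.array([tau_b[1], tau_spine_b[1]])
        starts = [
            np.clip(np.array([s, _crude_tau_init(t, y)]), lo, hi)
            for s in (2.0, 10.0, 40.0)
        ]
        fixed = ()
    else:

        def residuals(p):
            return (y - survival(TwoStageDecay(p[0], tau_spine_fixed), t)) / y

        lo, hi = np.array([tau_b[0]]), np.array([tau_b[1]])
        starts = [np.clip(np.array([s]), lo, hi) for s in (2.0, 10.0, 40.0)]
        fixed = ("tau_spine",)

    best = None
    ok = False
    for p0 in starts:
        res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        if best is None or res.cost < best.cost:
            best, ok = res, bool(res.success)
    if fit_tau_spine:
        model = TwoStageDecay(float(best.x[0]), float(best.x[1]))
    else:
        model = TwoStageDecay(float(best.x[0]), float(tau_spine_fixed))
    return DecayFit(
        model=model,
        weighted_sse=float(2.0 * best.cost),
        n_points=len(t),
        fixed_parameters=fixed,
        converged=ok,
    )
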