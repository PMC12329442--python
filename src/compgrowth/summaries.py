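"""Posterior-derived scientific outputs.

Three kinds of summary are produced from a fitted posterior:

* *age-weighted parameter trajectories* — at each age, the five processes'
  q, K or H values are averaged with weights proportional to each process's
  contribution to overall height; for the metabolic parameters K and H the
  weights additionally carry a metabolic-activity factor that declines
  linearly in relative component height from 1 at initiation to ``1 - rho``
  at the asymptote (``rho = 0.75`` by default, modelling the replacement of
  metabolically active red marrow by marrow fat as a process completes);
* *trajectory descriptives* — maximum achieved height (read at a reference
  adult age), peak pubertal growth velocity, and the age at that peak;
* HPDI bands and group contrasts for either of the above.

Weighted values are convex combinations, so every weighted trajectory lies
inside the envelope of the five process-level parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_prep import GESTATION_YR
from .growth_core import ComponentParams, CompositeParams, asymptotic_height
from .inference import PosteriorDraws, hpdi
from .transforms import N_TRANSFORMED, natural_array

__all__ = [
    "process_weights",
    "metabolic_activity",
    "WeightedParamTrajectory",
    "weighted_parameter_trajectory",
    "TrajectoryDescriptives",
    "trajectory_descriptives",
    "group_mean_curve",
    "trajectory_table",
]


def _component_heights(nat: np.ndarray, t: np.ndarray, D: float = 1.0) -> np.ndarray:
    """Vectorized component heights: nat (..., 4, 5), t (T,) -> (..., T, 5)."""
    H = nat[..., 0, :][..., None, :]
    K = nat[..., 1, :][..., None, :]
    q = nat[..., 2, :][..., None, :]
    i0 = nat[..., 3, :][..., None, :]
    tt = t[..., :, None]
    lam = K * q / (1.0 + 2.0 * q)
    arg = np.minimum(lam * (i0 - tt), 0.0)
    b = (2.0 * H / (D * K)) * np.clip(1.0 - np.exp(arg), 0.0, None)
    b = np.where(tt >= i0, b, 0.0)
    return b ** (1.0 / q)


def _component_velocity(nat: np.ndarray, t: np.ndarray, D: float = 1.0) -> np.ndarray:
    """Vectorized total dh/dt on a grid: (...,) x (T,) -> (..., T)."""
    h = _component_heights(nat, t, D)
    H = nat[..., 0, :][..., None, :]
    K = nat[..., 1, :][..., None, :]
    q = nat[..., 2, :][..., None, :]
    denom = 1.0 + 2.0 * q
    with np.errstate(invalid="ignore"):
        v = h ** (1.0 - q) * (2.0 * H / (D * denom) - (K / denom) * h**q)
    return np.where(h > 0.0, v, 0.0).sum(axis=-1)


def process_weights(cp: CompositeParams, t: float) -> np.ndarray:
    """Fractional contribution of each process to overall height at age t."""
    from .growth_core import component_height

    h = np.array([component_height(c, t, cp.D) for c in cp.components])
    total = h.sum()
    if total <= 0:
        raise ValueError(f"composite height is zero at t={t}; weights undefined")
    return h / total


def metabolic_activity(p: ComponentParams, t, rho: float = 0.75):
    """Relative metabolic activity of one process: 1 - rho * h(t)/h_inf.

    Declines from 1 at initiation to ``1 - rho`` at the asymptote.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    from .growth_core import component_height

    h = np.asarray(component_height(p, t), dtype=float)
    a = 1.0 - rho * h / asymptotic_height(p)
    return a if a.ndim else float(a)


@dataclass
class WeightedParamTrajectory:
    """Per-draw age-weighted values of one parameter family for one group."""

    ages: np.ndarray  # total ages (yr)
    values: np.ndarray  # (n_draws, n_ages); NaN where undefined
    family: str
    group: str
    rho: float
    mass: float = 0.9

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    def bands(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.ages.size)
        hi = np.empty(self.ages.size)
        for k in range(self.ages.size):
            col = self.values[:, k]
            col = col[np.isfinite(col)]
            if col.size < 2:
                lo[k] = hi[k] = np.nan
            else:
                lo[k], hi[k] = hpdi(col, self.mass)
        return lo, hi


def weighted_parameter_trajectory(
    posterior: PosteriorDraws,
    family: str,
    ages: Sequence[float],
    group: Optional[str] = None,
    rho: float = 0.75,
    mass: float = 0.9,
) -> WeightedParamTrajectory:
    """Age-weighted population-mean parameter trajectory for one group.

    Per draw and age, with process weights ``w_x = h_x / sum h`` and
    activities ``a_x = 1 - rho h_x / h_inf,x``:

    * family ``q``:      qbar = sum(w q) / sum(w)
    * family ``K``/``H``: Kbar = sum(w a K) / sum(w a)   (H analogous)

    Ages with zero composite height yield NaN (reported missing).
    """
    if family not in ("q", "K", "H"):
        raise ValueError("family must be one of 'q', 'K', 'H'")
    group = group or posterior.group_labels[0]
    ages = np.asarray(ages, dtype=float)
    theta = posterior.group_level(group)  # (n, 19)
    nat = natural_array(theta)  # (n, 4, 5)
    h = _component_heights(nat, ages)  # (n, T, 5)
    total = h.sum(axis=-1)
    fam_idx = {"H": 0, "K": 1, "q": 2}[family]
    vals = nat[:, fam_idx, :][:, None, :]  # (n, 1, 5)
    if family == "q":
        w = h
    else:
        A = (2.0 * nat[:, 0, :] / nat[:, 1, :]) ** (1.0 / nat[:, 2, :])
        act = 1.0 - rho * h / A[:, None, :]
        w = h * act
    denom = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w * vals).sum(axis=-1) / denom
    out[total <= 0.0] = np.nan
    return WeightedParamTrajectory(
        ages=ages, values=out, family=family, group=group, rho=rho, mass=mass
    )


@dataclass
class TrajectoryDescriptives:
    """Per-draw trajectory characteristics for one group."""

    max_height: np.ndarray  # cm, at the reference adult age
    peak_velocity: np.ndarray  # cm/yr within the search window
    age_at_peak: np.ndarray  # yr since birth
    degenerate: np.ndarray  # True where the peak sits on the window edge
    group: str
    window: tuple[float, float]
    reference_age: float
    mass: float = 0.9

    def intervals(self) -> dict:
        return {
            "max_height": hpdi(self.max_height, self.mass),
            "peak_velocity": hpdi(self.peak_velocity, self.mass),
            "age_at_peak": hpdi(self.age_at_peak, self.mass),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("max_height", "peak_velocity", "age_at_peak"):
            arr = getattr(self, name)
            lo, hi = hpdi(arr, self.mass)
            rows.append(
                dict(group=self.group, quantity=name, mean=float(arr.mean()),
                     hpdi_lo=lo, hpdi_hi=hi)
            )
        return pd.DataFrame(rows)


def trajectory_descriptives(
    posterior: PosteriorDraws,
    group: Optional[str] = None,
    window: tuple[float, float] = (5.0, 20.0),
    reference_age: float = 26.0,
    grid_step: float = 0.01,
    mass: float = 0.9,
) -> TrajectoryDescriptives:
    """Max height, peak pubertal velocity and its age, per posterior draw.

    ``window`` and ``reference_age`` are ages since birth; the velocity
    maximum is located on a ``grid_step``-yr grid and refined by parabolic
    interpolation through the neighbouring grid points (earliest age on
    exact ties).  Draws whose maximum sits at the window edge (no interior
    pubertal peak) are flagged degenerate.
    """
    group = group or posterior.group_labels[0]
    theta = posterior.group_level(group)
    nat = natural_array(theta)
    max_h = _component_heights(nat, np.array([reference_age + GESTATION_YR]))
    max_h = max_h.sum(axis=-1)[:, 0]

    grid = np.arange(window[0], window[1] + grid_step / 2, grid_step) + GESTATION_YR
    v = _component_velocity(nat, grid)  # (n, T)
    k = np.argmax(v, axis=1)
    n = v.shape[0]
    peak_t = grid[k].copy()
    peak_v = v[np.arange(n), k].copy()
    interior = (k > 0) & (k < grid.size - 1)
    if np.any(interior):
        km = k[interior]
        y0 = v[interior, km - 1]
        y1 = v[interior, km]
        y2 = v[interior, km + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        peak_t[interior] = grid[km] + shift * grid_step
        peak_v[interior] = y1 - 0.25 * (y0 - y2) * shift
    return TrajectoryDescriptives(
        max_height=max_h,
        peak_velocity=peak_v,
        age_at_peak=peak_t - GESTATION_YR,
        degenerate=~interior,
        group=group,
        window=window,
        reference_age=reference_age,
        mass=mass,
    )


def group_mean_curve(
    posterior: PosteriorDraws,
    group: str,
    ages: Sequence[float],
    kind: str = "height",
) -> np.ndarray:
    """Per-draw population-mean trajectory of a group: (n_draws, n_ages)."""
    ages = np.asarray(ages, dtype=float)
    nat = natural_array(posterior.group_level(group))
    h = _component_heights(nat, ages)
    if kind == "height":
        return h.sum(axis=-1)
    if kind == "mass":
        q = nat[:, 2, :][:, None, :]
        return np.pi * (h ** (1.0 + 2.0 * q)).sum(axis=-1)
    if kind == "velocity":
        return _component_velocity(nat, ages)
    raise ValueError("kind must be 'height', 'mass' or 'velocity'")


def trajectory_table(
    posterior: PosteriorDraws,
    ages: Sequence[float],
    rho: float = 0.75,
    mass: float = 0.9,
) -> pd.DataFrame:
    """Tidy table (age, group, family, mean, hpdi_lo, hpdi_hi) of weighted
    parameter trajectories for every group and family."""
    rows = []
    for group in posterior.group_labels:
        for family in ("q", "K", "H"):
            wt = weighted_parameter_trajectory(
                posterior, family, ages, group=group, rho=rho, mass=mass
            )
            lo, hi = wt.bands()
            for k, age in enumerate(wt.ages):
                rows.append(
                    dict(
                        age=float(age),
                        group=group,
                        family=family,
                        mean=float(wt.mean[k]),
                        hpdi_lo=float(lo[k]),
                        hpdi_hi=float(hi[k]),
                    )
                )
    return pd.DataFrame(rows)
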