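"""Quadratic response surface of the browning score over time and temperature.

The whole-cookie browning score S is modelled as a full 6-term quadratic in
baking time x1 (min) and oven temperature x2 (degC):

    S = b0 + b1*x1 + b2*x2 + b11*x1^2 + b22*x2^2 + b12*x1*x2

fit by ordinary least squares over the experimental grid.  The fitted surface
is valid only inside the investigated box (4-16 min, 150-200 degC); extreme
bakes (20 min) are excluded from fitting.  The analytic gradient gives the
time/temperature sensitivity ratio (degC of oven change equivalent to one
minute of baking), and thresholding the surface with the sensory class limits
draws the under/adequate/overbaked zones of the process window.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["ResponseSurface", "fit_surface", "sensitivity_ratio", "zone_map"]


@dataclasses.dataclass
class ResponseSurface:
    """Six quadratic coefficients with their validity box."""

    b0: float
    b1: float
    b2: float
    b11: float
    b22: float
    b12: float
    time_range: tuple[float, float] = (4.0, 16.0)
    temp_range: tuple[float, float] = (150.0, 200.0)

    def __post_init__(self) -> None:
        coefs = (self.b0, self.b1, self.b2, self.b11, self.b22, self.b12)
        if not np.all(np.isfinite(coefs)):
            raise ValueError("surface coefficients must be finite")

    def _check_box(self, time_min, temp_c) -> None:
        t, T = np.asarray(time_min), np.asarray(temp_c)
        if np.any(t < self.time_range[0]) or np.any(t > self.time_range[1]) or np.any(
            T < self.temp_range[0]
        ) or np.any(T > self.temp_range[1]):
            warnings.warn(
                f"evaluating outside the validity box {self.time_range} min x "
                f"{self.temp_range} degC",
                stacklevel=3,
            )

    def evaluate(self, time_min, temp_c, check: bool = True):
        """Surface value; warns (but still computes) outside the validity box."""
        if check:
            self._check_box(time_min, temp_c)
        t = np.asarray(time_min, float)
        T = np.asarray(temp_c, float)
        out = (
            self.b0 + self.b1 * t + self.b2 * T
            + self.b11 * t**2 + self.b22 * T**2 + self.b12 * t * T
        )
        return float(out) if out.ndim == 0 else out

    def gradient(self, time_min: float, temp_c: float) -> tuple[float, float]:
        """Analytic (dS/dtime, dS/dtemp) at a point."""
        ds_dt = self.b1 + 2.0 * self.b11 * time_min + self.b12 * temp_c
        ds_dT = self.b2 + 2.0 * self.b22 * temp_c + self.b12 * time_min
        return float(ds_dt), float(ds_dT)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ResponseSurface":
        d = json.loads(Path(path).read_text())
        return cls(
            b0=d["b0"], b1=d["b1"], b2=d["b2"], b11=d["b11"], b22=d["b22"], b12=d["b12"],
            time_range=tuple(d["time_range"]), temp_range=tuple(d["temp_range"]),
        )


def _basis(t: np.ndarray, T: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, T, t**2, T**2, t * T])


def fit_surface(
    mean_scores: Sequence[float],
    times: Sequence[float],
    temps: Sequence[float],
    exclude_times: Sequence[float] = (20.0,),
) -> tuple[ResponseSurface, np.ndarray]:
    """OLS fit of the 6-term quadratic; returns (surface, residuals).

    Extreme baking times (default 20 min) are dropped before fitting.  The
    design must contain at least six distinct (time, temperature) points of
    full quadratic rank.
    """
    y = np.asarray(mean_scores, float)
    t = np.asarray(times, float)
    T = np.asarray(temps, float)
    if not (y.shape == t.shape == T.shape):
        raise ValueError("scores, times and temps must have equal length")
    keep = ~np.isin(t, np.asarray(exclude_times, float))
    y, t, T = y[keep], t[keep], T[keep]
    if len(set(zip(t.tolist(), T.tolist()))) < 6:
        raise ValueError("need at least six distinct (time, temperature) design points")
    A = _basis(t, T)
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 6:
        raise ValueError("rank-deficient design: quadratic surface not identifiable")
    surface = ResponseSurface(
        b0=float(coef[0]), b1=float(coef[1]), b2=float(coef[2]),
        b11=float(coef[3]), b22=float(coef[4]), b12=float(coef[5]),
        time_range=(float(t.min()), float(t.max())),
        temp_range=(float(T.min()), float(T.max())),
    )
    residuals = y - A @ coef
    return surface, residuals


def sensitivity_ratio(surface: ResponseSurface, at_time: float, at_temp: float) -> float:
    """degC of oven change equivalent to one minute of baking at a point.

    ``(dS/dtime) / (dS/dtemp)`` from the analytic gradient; an exact
    time-temperature trade-off of 10 degC/min gives 10 everywhere.
    """
    surface._check_box(at_time, at_temp)
    ds_dt, ds_dT = surface.gradient(at_time, at_temp)
    if ds_dT == 0:
        raise ValueError("temperature sensitivity is zero at this point (stationary)")
    return ds_dt / ds_dT


def zone_map(
    surface: ResponseSurface,
    limits: tuple[float, float],
    time_grid: Sequence[float],
    temp_grid: Sequence[float],
) -> np.ndarray:
    """Browning-stage zones over a (temp x time) grid.

    Each cell is the surface value thresholded with the sensory class limits;
    codes are 0 underbaked, 1 adequately baked, 2 overbaked.  Rows follow
    ``temp_grid``, columns ``time_grid``.  Grids outside the validity box
    warn but are still computed.
    """
    limit_ua, limit_ao = limits
    tt, TT = np.meshgrid(np.asarray(time_grid, float), np.asarray(temp_grid, float))
    surface._check_box(tt, TT)
    vals = surface.evaluate(tt, TT, check=False)
    zones = np.full(vals.shape, 1, dtype=np.int8)
    zones[vals > limit_ua] = 0
    zones[vals <= limit_ao] = 2
    return zones
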