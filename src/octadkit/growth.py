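"""Generation-time estimation from growth curves, plus a synthetic
growth-curve generator.

The doubling time is estimated by linear regression of log2(density) on
time within an exponential-phase window.  When no window is given, the
fitter auto-detects the exponential phase in two passes.  First the noise
floor is estimated as the smallest residual variance among medium-length
windows (the straightest stretch of the curve).  Then, among all
contiguous windows of at least ``min_points`` readings with positive slope
and r² at or above a threshold, windows whose residual variance exceeds a
small multiple of the noise floor are discarded — they bend, i.e. they
leak into lag or saturation — and the longest surviving window wins (ties:
higher r², then earlier start).  A plain "maximise r²" rule degenerates
into a lottery among 4-point windows once readings are noisy, and a plain
"longest window above the r² gate" rule swallows the whole sigmoid, whose
r² is deceptively high; anchoring acceptance to the empirical noise floor
avoids both.  The selected window is always reported for auditability.

Densities are unitless OD-like readings; only their ratios matter, so the
estimate is invariant to rescaling the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "NoGrowthError",
    "PhaseDetectionError",
    "fit_doubling_time",
    "simulate_growth",
    "read_growth_tsv",
    "write_growth_tsv",
]


class NoGrowthError(ValueError):
    """The fitted slope is not positive: the culture is not growing."""


class PhaseDetectionError(ValueError):
    """No contiguous window qualifies as an exponential phase."""


@dataclass(frozen=True)
class GrowthCurve:
    """A culture density time series (times in minutes, densities > 0)."""

    times: np.ndarray
    densities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if t.ndim != 1 or d.ndim != 1 or len(t) != len(d):
            raise ValueError("times and densities must be 1-D and equal length")
        if len(t) < 2:
            raise ValueError("a growth curve needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(d > 0):
            raise ValueError("densities must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "densities", d)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthFit:
    """Result of an exponential-phase fit.

    ``window`` is the fitted range as slice-style indices (start, stop);
    ``slope`` is the log2-density rate per minute, so
    ``doubling_time = 1 / slope``.
    """

    doubling_time: float
    window: tuple[int, int]
    slope: float
    r_squared: float
    label: str = ""

    @property
    def n_points(self) -> int:
        return self.window[1] - self.window[0]


def _regress(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, r² and residual sum of squares of y on t."""
    t = t - t.mean()
    y0 = y - y.mean()
    stt = float(t @ t)
    sty = float(t @ y0)
    syy = float(y0 @ y0)
    slope = sty / stt
    ssr = max(syy - sty * sty / stt, 0.0)
    if syy == 0.0:
        return slope, 1.0, 0.0  # flat line fits itself exactly (slope 0)
    r2 = (sty * sty) / (stt * syy)
    return slope, r2, ssr


def fit_doubling_time(
    curve: GrowthCurve,
    window: Optional[tuple[int, int]] = None,
    min_points: int = 4,
    r2_threshold: float = 0.98,
    noise_window: int = 8,
    noise_factor: float = 4.0,
) -> GrowthFit:
    """Estimate the doubling time of *curve* from its exponential phase.

    Parameters
    ----------
    curve : GrowthCurve
    window : (start, stop), optional
        Explicit index range (slice convention) to fit.  When given, any
        length >= 2 is accepted and no r² gate applies.  When omitted, the
        longest contiguous window of >= *min_points* points with positive
        slope, r² >= *r2_threshold* and residual variance consistent with
        the curve's noise floor is selected automatically (see module
        docstring).
    min_points, r2_threshold
        Gates for the automatic window search.
    noise_window, noise_factor
        The noise floor is the smallest residual variance among windows of
        *noise_window* points; candidate windows may exceed it by at most
        *noise_factor*.

    Raises
    ------
    NoGrowthError
        The explicit window has non-positive slope.
    PhaseDetectionError
        No window qualifies in the automatic search.
    """
    y = np.log2(curve.densities)
    t = curve.times
    if window is not None:
        start, stop = window
        if not (0 <= start < stop <= len(curve)) or stop - start < 2:
            raise ValueError(f"invalid window {window} for {len(curve)} points")
        slope, r2, _ssr = _regress(t[start:stop], y[start:stop])
        if slope <= 0:
            raise NoGrowthError(
                f"slope {slope:.3g}/min in window {window} is not positive"
            )
        return GrowthFit(
            doubling_time=1.0 / slope,
            window=(start, stop),
            slope=slope,
            r_squared=r2,
            label=curve.label,
        )

    n = len(curve)
    if n < min_points:
        raise PhaseDetectionError(
            f"curve has {n} points; automatic detection needs >= {min_points}"
        )
    # noise floor: the straightest noise_window-point stretch of the curve
    m0 = min(max(noise_window, min_points), n)
    floor = min(
        _regress(t[s : s + m0], y[s : s + m0])[2] / (m0 - 2)
        for s in range(n - m0 + 1)
    )
    max_resid_var = max(noise_factor * floor, 1e-12)

    best: Optional[tuple[int, float, int, float]] = None  # (len, r2, -start, slope)
    best_window: Optional[tuple[int, int]] = None
    for length in range(min_points, n + 1):
        for start in range(0, n - length + 1):
            stop = start + length
            slope, r2, ssr = _regress(t[start:stop], y[start:stop])
            if slope <= 0 or r2 < r2_threshold:
                continue
            if ssr / (length - 2) > max_resid_var:
                continue
            key = (length, r2, -start, slope)
            if best is None or key > best:
                best = key
                best_window = (start, stop)
    if best is None or best_window is None:
        overall_slope, _, _ = _regress(t, y)
        if overall_slope <= 0:
            raise NoGrowthError(
                f"overall slope {overall_slope:.3g}/min is not positive; "
                f"the culture is not growing"
            )
        raise PhaseDetectionError(
            f"no contiguous window of >= {min_points} points reaches "
            f"r^2 >= {r2_threshold} with positive slope and noise-consistent "
            f"residuals"
        )
    length, r2, _, slope = best
    return GrowthFit(
        doubling_time=1.0 / slope,
        window=best_window,
        slope=slope,
        r_squared=r2,
        label=curve.label,
    )


def simulate_growth(
    lag: float = 60.0,
    doubling_time: float = 63.0,
    carrying_capacity: float = 8.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    initial_density: float = 0.01,
    t_end: float = 720.0,
    dt: float = 15.0,
    label: str = "",
) -> GrowthCurve:
    """Generate a synthetic growth curve: lag, exponential phase at the
    stated doubling time, logistic saturation at the carrying capacity,
    multiplicative log-normal noise.

    ``noise_sd`` is the standard deviation of the log-density perturbation
    (≈ relative error for small values).  Deterministic per seed.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    if carrying_capacity <= initial_density:
        raise ValueError("carrying capacity must exceed the initial density")
    times = np.arange(0.0, t_end + dt / 2, dt)
    rate = np.log(2.0) / doubling_time
    s = np.maximum(times - lag, 0.0)
    growth = np.exp(rate * s)
    dens = (
        carrying_capacity
        * initial_density
        * growth
        / (carrying_capacity + initial_density * (growth - 1.0))
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dens = dens * np.exp(rng.normal(0.0, noise_sd, size=dens.shape))
    return GrowthCurve(times=times, densities=dens, label=label)


def read_growth_tsv(path: Union[str, Path], label: str = "") -> GrowthCurve:
    """Read a growth curve from TSV with columns ``time_min``, ``density``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_min", "density"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return GrowthCurve(
        times=df["time_min"].to_numpy(float),
        densities=df["density"].to_numpy(float),
        label=label or str(path),
    )


def write_growth_tsv(curve: GrowthCurve, path: Union[str, Path]) -> None:
    pd.DataFrame({"time_min": curve.times, "density": curve.densities}).to_csv(
        path, sep="\t", index=False
    )
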