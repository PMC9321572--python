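"""Environmental time series with spline smoothing.

An :class:`EnvCurve` holds an (age, value) table — e.g. a paleotemperature
record, ages in Myr before present — and exposes a smoothed, everywhere-
evaluable function of age.  The smoother is a least-squares cubic B-spline
whose number of coefficients plays the role of the degrees of freedom of
R's ``smooth.spline`` (default 33, the smoothing conventionally applied to
Phanerozoic temperature curves before rate modelling).  Outside the
tabulated age range the smoothed fit is extended linearly, with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_lsq_spline, CubicSpline

__all__ = ["EnvCurve"]


class EnvCurve:
    def __init__(self, ages, values, df: int = 33) -> None:
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages.ndim != 1 or ages.shape != values.shape:
            raise ValueError("ages and values must be 1-D and equal length")
        if ages.size < 2:
            raise ValueError("need at least two (age, value) points")
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative (Myr before present)")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        self.ages = ages
        self.values = values
        self.df = int(df)
        self._fit()

    def _fit(self) -> None:
        k = 3
        n = self.ages.size
        # number of B-spline coefficients = df, capped by the data
        ncoef = int(np.clip(self.df, k + 1, n))
        if ncoef >= n:
            # saturated: interpolate
            self._spline = CubicSpline(self.ages, self.values)
        else:
            n_interior = ncoef - k - 1
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(self.ages, qs)
            t = np.concatenate(
                [[self.ages[0]] * (k + 1), interior, [self.ages[-1]] * (k + 1)]
            )
            self._spline = make_lsq_spline(self.ages, self.values, t, k=k)
        a, b = self.ages[0], self.ages[-1]
        eps = (b - a) * 1e-6
        self._lo, self._hi = a, b
        self._slope_lo = (self._spline(a + eps) - self._spline(a)) / eps
        self._slope_hi = (self._spline(b) - self._spline(b - eps)) / eps

    def __call__(self, age):
        """Smoothed value at ``age`` (scalar or array), Myr before present."""
        age = np.asarray(age, dtype=float)
        scalar = age.ndim == 0
        age = np.atleast_1d(age)
        out = np.asarray(self._spline(np.clip(age, self._lo, self._hi)), dtype=float)
        below = age < self._lo
        above = age > self._hi
        if below.any() or above.any():
            warnings.warn(
                "environment curve evaluated outside its age range; "
                "extending linearly",
                stacklevel=2,
            )
            out[below] = self._spline(self._lo) + self._slope_lo * (
                age[below] - self._lo
            )
            out[above] = self._spline(self._hi) + self._slope_hi * (
                age[above] - self._hi
            )
        return float(out[0]) if scalar else out

    @property
    def age_range(self) -> tuple[float, float]:
        return (self._lo, self._hi)

    def is_constant(self, rtol: float = 1e-10) -> bool:
        span = np.ptp(self.values)
        scale = max(1.0, np.max(np.abs(self.values)))
        return bool(span <= rtol * scale)

    # -- I/O ----------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str, df: int = 33) -> "EnvCurve":
        """Read columns ``age_ma,value``."""
        tab = pd.read_csv(path)
        tab = tab.sort_values("age_ma")
        return cls(tab["age_ma"].to_numpy(), tab["value"].to_numpy(), df=df)

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"age_ma": self.ages, "value": self.values}).to_csv(
            path, index=False
        )
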