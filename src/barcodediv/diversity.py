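"""Sampling-completeness assessment.

Rarefaction of accession records, incidence-based Chao2 richness, and the
sampling fractions passed to the diversification likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceTable",
    "RichnessEstimate",
    "rarefaction_curve",
    "chao2_richness",
    "sampling_fraction",
]


@dataclass
class IncidenceTable:
    """Binary unit-by-sample incidence matrix."""

    units: list[str]
    samples: list[str]
    matrix: np.ndarray  # shape (n_units, n_samples), entries {0,1}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.units), len(self.samples)):
            raise ValueError("incidence matrix shape mismatch")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        if (m.sum(axis=1) == 0).any():
            raise ValueError("incidence table contains empty units")
        self.matrix = m.astype(np.int8)

    @classmethod
    def from_records(cls, records: pd.DataFrame, unit_col="unit", sample_col="sample"):
        """Build from long-format (unit, sample) occurrence records."""
        pivot = (
            records.assign(_one=1)
            .pivot_table(index=unit_col, columns=sample_col, values="_one", aggfunc="max", fill_value=0)
        )
        return cls(list(pivot.index), list(pivot.columns), pivot.to_numpy())

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class RichnessEstimate:
    s_obs: int
    estimate: float
    fraction: float  # s_obs / estimate, in (0, 1]
    ci_low: float
    ci_high: float
    q1: int
    q2: int
    n_samples: int
    estimator: str = "Chao2"


def chao2_richness(inc: IncidenceTable) -> RichnessEstimate:
    """Chao2 incidence-based richness with a log-normal interval.

    With Q1 uniques, Q2 duplicates and R samples:
    ``S = S_obs + ((R-1)/R) * Q1^2 / (2 Q2)`` when Q2 > 0, else the
    bias-corrected ``S = S_obs + ((R-1)/R) * Q1 (Q1 - 1) / 2``.  The 95%
    interval uses the classical log-normal approximation on S - S_obs.
    """
    R = inc.n_samples
    if R < 2:
        raise ValueError("Chao2 needs at least two samples")
    freq = inc.matrix.sum(axis=1)
    s_obs = len(inc.units)
    q1 = int((freq == 1).sum())
    q2 = int((freq == 2).sum())
    A = (R - 1) / R
    if q2 > 0:
        est = s_obs + A * q1 * q1 / (2.0 * q2)
        ratio = q1 / q2
        var = q2 * (
            0.5 * A * ratio**2 + A**2 * ratio**3 + 0.25 * A**2 * ratio**4
        )
    else:
        est = s_obs + A * q1 * (q1 - 1) / 2.0
        var = (
            A * q1 * (q1 - 1) / 2.0
            + A**2 * q1 * (2 * q1 - 1) ** 2 / 4.0
            - (A * q1) ** 2 * q1**2 / (4.0 * est)
            if est > 0
            else 0.0
        )
    T = est - s_obs
    if T > 0 and var > 0:
        K = np.exp(1.96 * np.sqrt(np.log1p(var / T**2)))
        lo, hi = s_obs + T / K, s_obs + T * K
    else:
        lo = hi = float(est)
    return RichnessEstimate(
        s_obs=s_obs,
        estimate=float(est),
        fraction=s_obs / float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        q1=q1,
        q2=q2,
        n_samples=R,
    )


def rarefaction_curve(
    accession_to_unit: Mapping[str, str] | pd.Series,
    step: float = 0.05,
    reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Median rarefied richness on a regular grid of sampled fractions.

    Accessions (sequence records) are subsampled without replacement;
    at each grid fraction the median distinct-unit count over ``reps``
    independent subsamples is reported.  Columns: ``fraction``, ``n_accessions``,
    ``median_richness``, ``q25``, ``q75``.
    """
    if isinstance(accession_to_unit, pd.Series):
        units = accession_to_unit.to_numpy()
    else:
        units = np.asarray(list(accession_to_unit.values()))
    N = units.size
    if N < 1:
        raise ValueError("need at least one accession")
    if not (0 < step <= 1):
        raise ValueError("step must be in (0, 1]")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        warnings.warn(f"step {step} does not divide 1; grid rounded to {n_steps} steps")
    fractions = np.arange(1, n_steps + 1) / n_steps
    sizes = np.maximum(1, np.round(fractions * N).astype(int))
    _, codes = np.unique(units, return_inverse=True)
    n_units_total = codes.max() + 1
    rng = np.random.default_rng(seed)
    rich = np.empty((reps, len(sizes)), dtype=int)
    for r in range(reps):
        perm = codes[rng.permutation(N)]
        seen = np.zeros(n_units_total, dtype=bool)
        cum = np.empty(N, dtype=int)
        c = 0
        for i, u in enumerate(perm):
            if not seen[u]:
                seen[u] = True
                c += 1
            cum[i] = c
        rich[r] = cum[sizes - 1]
    return pd.DataFrame(
        {
            "fraction": fractions,
            "n_accessions": sizes,
            "median_richness": np.median(rich, axis=0),
            "mean_richness": rich.mean(axis=0),
            "q25": np.quantile(rich, 0.25, axis=0),
            "q75": np.quantile(rich, 0.75, axis=0),
        }
    )


def sampling_fraction(
    observed: float, estimated_total: float, percent: bool = False
) -> float:
    """Observed richness over estimated total richness.

    ``percent=True`` reports to the nearest percent (the convention of
    completeness tables).
    """
    if not (0 < observed <= estimated_total):
        raise ValueError("need 0 < observed <= estimated_total")
    f = observed / estimated_total
    return float(round(100.0 * f)) if percent else f
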