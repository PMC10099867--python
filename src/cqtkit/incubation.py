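"""Reference-temperature correlation sweep for soil-incubation data.

Each incubation contributes a fitted exponential temperature response
(Q10, ln R0). Because the response is log-linear, the ln rate at any
reference temperature T is ``ln R_T = ln R0 + (ln Q10 / 10)·T``, so the
whole response curve is recoverable from the two fitted parameters.

The sweep computes the correlation between Q10 and ln R_T across a grid
of reference temperatures. Under the carbon-quality temperature (CQT)
hypothesis this correlation should be negative *regardless* of T; in
practice it flips sign at a data-dependent temperature, which is what
makes "rate at a reference temperature" an invalid carbon-quality index.
The flip temperature has the closed form

    T0 = −cov(Q10, ln R0) / cov(Q10, b),      b = ln(Q10)/10,

because cov(Q10, ln R_T) = cov(Q10, ln R0) + T·cov(Q10, b) is linear in T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "IncubationRecord",
    "SweepResult",
    "reconstruct_ln_rate",
    "pearson_correlation",
    "correlation_sweep",
    "sign_flip_temperature",
]


@dataclass(frozen=True)
class IncubationRecord:
    """One incubation's fitted temperature response.

    Attributes
    ----------
    id:
        Record label, unique within a dataset.
    source:
        Dataset of origin (free text).
    q10:
        Temperature sensitivity, dimensionless, > 0.
    ln_r0:
        Natural log of the respiration rate at 0°C.
    """

    id: str
    source: str
    q10: float
    ln_r0: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.q10) or self.q10 <= 0:
            raise InvalidArgumentError(
                f"record {self.id!r}: q10 must be finite and > 0, got {self.q10}"
            )
        if not math.isfinite(self.ln_r0):
            raise InvalidArgumentError(
                f"record {self.id!r}: ln_r0 must be finite, got {self.ln_r0}"
            )

    @property
    def b(self) -> float:
        """Exponential-model slope ``ln(q10)/10`` per °C."""
        return math.log(self.q10) / 10.0


@dataclass(frozen=True)
class SweepResult:
    """Correlation-versus-reference-temperature profile.

    ``r[i]`` and ``p[i]`` are the correlation coefficient and two-sided
    p-value between Q10 and the reconstructed ln rate at
    ``temperatures[i]`` (°C); ``n`` is the number of records.
    """

    temperatures: np.ndarray
    r: np.ndarray
    p: np.ndarray
    n: int

    def r_at(self, t_celsius: float) -> float:
        """Correlation at the grid point nearest ``t_celsius``."""
        idx = int(np.argmin(np.abs(self.temperatures - t_celsius)))
        return float(self.r[idx])

    def zero_crossings(self) -> list[float]:
        """Grid temperatures bracketing each sign change of r(T),
        linearly interpolated."""
        crossings = []
        r, t = self.r, self.temperatures
        for i in range(len(r) - 1):
            if r[i] == 0.0:
                crossings.append(float(t[i]))
            elif r[i] * r[i + 1] < 0:
                frac = r[i] / (r[i] - r[i + 1])
                crossings.append(float(t[i] + frac * (t[i + 1] - t[i])))
        if r[-1] == 0.0:
            crossings.append(float(t[-1]))
        return crossings


def reconstruct_ln_rate(rec: IncubationRecord, t: float) -> float:
    """Natural-log respiration rate of ``rec`` at temperature ``t`` (°C)."""
    return rec.ln_r0 + rec.b * float(t)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (n−2 df).

    Raises
    ------
    DegenerateInputError
        If fewer than 3 pairs or either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-d and of equal length")
    if x.size < 3:
        raise DegenerateInputError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _sorted_arrays(records: Sequence[IncubationRecord]):
    """Record arrays in a canonical order so results are bit-identical
    under permutation of the input."""
    q10 = np.array([r.q10 for r in records], dtype=float)
    lnr0 = np.array([r.ln_r0 for r in records], dtype=float)
    order = np.lexsort((lnr0, q10))
    return q10[order], lnr0[order]


def correlation_sweep(
    records: Sequence[IncubationRecord],
    t_min: float = 0.0,
    t_max: float = 60.0,
    step: float = 1.0,
    method: str = "pearson",
) -> SweepResult:
    """Correlation between Q10 and reconstructed ln rate over a temperature grid.

    Parameters
    ----------
    records:
        At least 3 incubation records with non-constant Q10.
    t_min, t_max, step:
        Grid in °C, inclusive of both endpoints; default 0–60°C at 1°C.
    method:
        ``"pearson"`` (default) or ``"spearman"``.

    Returns
    -------
    SweepResult
        r(T) is continuous in T and equals corr(Q10, ln R0) at T=0.
    """
    if len(records) < 3:
        raise DegenerateInputError(f"need at least 3 records, got {len(records)}")
    if step <= 0 or t_max < t_min:
        raise InvalidArgumentError("grid requires step > 0 and t_max >= t_min")
    q10, lnr0 = _sorted_arrays(records)
    if np.ptp(q10) == 0:
        raise DegenerateInputError("all q10 equal: correlation undefined")
    b = np.log(q10) / 10.0
    n_grid = int(round((t_max - t_min) / step)) + 1
    temps = t_min + step * np.arange(n_grid)
    r_vals = np.empty(n_grid)
    p_vals = np.empty(n_grid)
    for i, t in enumerate(temps):
        ln_rt = lnr0 + b * t
        if method == "pearson":
            if np.ptp(ln_rt) == 0:
                # all reconstructed rates coincide at this T (curves cross
                # in a single point); correlation is undefined there
                r_vals[i], p_vals[i] = np.nan, np.nan
                continue
            res = stats.pearsonr(q10, ln_rt)
        elif method == "spearman":
            res = stats.spearmanr(q10, ln_rt)
        else:
            raise InvalidArgumentError(f"unknown method {method!r}")
        r_vals[i] = res.statistic
        p_vals[i] = res.pvalue
    return SweepResult(temperatures=temps, r=r_vals, p=p_vals, n=len(records))


def sign_flip_temperature(records: Sequence[IncubationRecord]) -> float | None:
    """Temperature (°C) where corr(Q10, ln R_T) changes sign.

    Closed form ``T0 = −cov(Q10, ln R0) / cov(Q10, b)`` with sample
    covariances; r(T0) = 0 exactly under the Pearson sweep. Returns
    ``None`` (with a warning) when cov(Q10, b) vanishes, in which case
    the correlation never changes sign.
    """
    if len(records) < 3:
        raise DegenerateInputError(f"need at least 3 records, got {len(records)}")
    q10, lnr0 = _sorted_arrays(records)
    if np.ptp(q10) == 0:
        return None
    b = np.log(q10) / 10.0
    cov_q_b = float(np.cov(q10, b, ddof=1)[0, 1])
    cov_q_lnr0 = float(np.cov(q10, lnr0, ddof=1)[0, 1])
    if cov_q_b == 0.0:
        warnings.warn("cov(q10, b) is zero: no sign-flip temperature", stacklevel=2)
        return None
    return -cov_q_lnr0 / cov_q_b
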