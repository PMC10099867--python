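"""CQT test on uncatalysed and enzyme-catalysed reaction kinetics.

The chemically grounded carbon-quality index is the uncatalysed
(spontaneous, enzyme-free) rate constant k_non of a compound's
degradation reaction. Given each uncatalysed reaction's activation
energy Ea and its rate at 25°C, ln k_non can be extrapolated to any
temperature on the Arrhenius plot. The CQT test then asks whether
temperature sensitivity (Ea, equivalently Q10) correlates with
ln k_non(T):

* **uncatalysed set** — Ea of each uncatalysed reaction vs its own
  ln k_non(T); negatively correlated almost by construction (a higher
  barrier means a slower rate), so this set is a positive control for
  the reference-temperature artefact;
* **catalysed set** — Ea of each *enzyme-catalysed* reaction vs the
  ln k_non(T) of its paired uncatalysed counterpart. The two variables
  come from separate measurements, so this is a circularity-free test:
  no correlation at any reference temperature means the CQT hypothesis
  fails for enzymatic decomposition.

Correlations are jackknifed (leave-one-out) to attach a standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import kinetics
from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    LinkageError,
)
from .kinetics import ArrheniusParams, T_REF_DEFAULT, arrhenius_extrapolate

__all__ = [
    "ArrheniusReaction",
    "JackknifeEstimate",
    "CqtProfiles",
    "resolve_ea",
    "knon_profile",
    "jackknife_correlation",
    "cqt_test",
    "summarize_ranges",
]

#: Tolerance (kJ/mol) for agreement when both Ea and ΔH‡ are supplied.
EA_CONSISTENCY_TOL = 0.5


@dataclass(frozen=True)
class ArrheniusReaction:
    """One reaction's kinetic record.

    Uncatalysed rows carry ``ln_k25`` (natural log of the rate constant
    in s⁻¹ at 25°C); catalysed rows instead carry a ``pair_id`` naming
    their uncatalysed counterpart. Either ``ea`` (Arrhenius activation
    energy) or ``dh`` (Eyring enthalpy of activation ΔH‡) must be
    present, both in kJ·mol⁻¹.
    """

    id: str
    name: str = ""
    catalysed: bool = False
    pair_id: str | None = None
    ea: float | None = None
    dh: float | None = None
    t_ref: float = T_REF_DEFAULT
    ln_k25: float | None = None

    def __post_init__(self) -> None:
        if self.ea is None and self.dh is None:
            raise InvalidArgumentError(
                f"reaction {self.id!r}: at least one of ea/dh required"
            )
        if not self.catalysed and self.ln_k25 is None:
            raise InvalidArgumentError(
                f"uncatalysed reaction {self.id!r}: ln_k25 required"
            )
        if self.catalysed and self.pair_id is None:
            raise InvalidArgumentError(
                f"catalysed reaction {self.id!r}: pair_id required"
            )


@dataclass(frozen=True)
class JackknifeEstimate:
    """Leave-one-out mean and standard error of a correlation coefficient."""

    r_mean: float
    se: float
    n: int


@dataclass(frozen=True)
class CqtProfiles:
    """Per-temperature jackknife correlation profiles for the CQT test.

    ``uncatalysed[i]`` is the jackknife estimate of corr(Ea, ln k_non(T))
    over the uncatalysed set at ``temperatures[i]`` (°C); ``catalysed``
    is the analogous profile for catalysed Ea vs paired ln k_non, or
    ``None`` when no catalysed records were supplied.
    """

    temperatures: np.ndarray
    uncatalysed: list[JackknifeEstimate]
    catalysed: list[JackknifeEstimate] | None = field(default=None)


def resolve_ea(rec: ArrheniusReaction) -> float:
    """Activation energy (kJ·mol⁻¹) of a record, deriving it from ΔH‡
    via ``Ea = ΔH‡ + R·t_ref`` when only the Eyring enthalpy is given.

    When both are supplied and disagree by more than 0.5 kJ·mol⁻¹ a
    consistency warning is emitted and the directly reported Ea wins.
    """
    if rec.ea is not None and rec.dh is not None:
        implied = kinetics.ea_from_enthalpy(rec.dh, rec.t_ref)
        if abs(implied - rec.ea) > EA_CONSISTENCY_TOL:
            warnings.warn(
                f"reaction {rec.id!r}: ea={rec.ea} disagrees with "
                f"dh-implied {implied:.3f} kJ/mol; using ea",
                stacklevel=2,
            )
        return float(rec.ea)
    if rec.ea is not None:
        return float(rec.ea)
    return kinetics.ea_from_enthalpy(rec.dh, rec.t_ref)


def knon_profile(
    rec: ArrheniusReaction,
    t_min: float = 0.0,
    t_max: float = 200.0,
    step: float = 1.0,
) -> np.ndarray:
    """ln k_non across a °C grid for an uncatalysed reaction.

    Arrhenius extrapolation anchored at 25°C; the value at 25°C equals
    ``ln_k25`` exactly.
    """
    if rec.catalysed:
        raise InvalidArgumentError(
            f"reaction {rec.id!r} is catalysed: k_non profiles apply only "
            "to uncatalysed records"
        )
    params = ArrheniusParams(ea=resolve_ea(rec), ln_k_ref=rec.ln_k25)
    temps = _grid(t_min, t_max, step)
    return np.array(
        [arrhenius_extrapolate(params, t + kinetics.KELVIN_OFFSET) for t in temps]
    )


def _grid(t_min: float, t_max: float, step: float) -> np.ndarray:
    if step <= 0 or t_max < t_min:
        raise InvalidArgumentError("grid requires step > 0 and t_max >= t_min")
    n = int(round((t_max - t_min) / step)) + 1
    return t_min + step * np.arange(n)


def jackknife_correlation(
    x: Sequence[float], y: Sequence[float]
) -> JackknifeEstimate:
    """Jackknife (leave-one-out) Pearson correlation.

    Computes the n leave-one-out correlations r_i, their mean, and the
    jackknife standard error ``sqrt(((n−1)/n) · Σ (r_i − r̄)²)``.

    The estimate depends only on the multiset of observations, never on
    their order.

    Raises
    ------
    DegenerateInputError
        If n < 4, or any leave-one-out subset has zero variance (the
        message names the offending index).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-d and of equal length")
    n = x.size
    if n < 4:
        raise DegenerateInputError(
            f"jackknife needs n >= 4 so every subset has >= 3 points, got {n}"
        )
    # canonical pair order => bit-identical estimates under relabeling
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    # all n leave-one-out subsets as rows of (n, n-1) matrices
    keep = ~np.eye(n, dtype=bool)
    x_loo = np.broadcast_to(x, (n, n))[keep].reshape(n, n - 1)
    y_loo = np.broadcast_to(y, (n, n))[keep].reshape(n, n - 1)
    for i in range(n):
        if np.ptp(x_loo[i]) == 0 or np.ptp(y_loo[i]) == 0:
            raise DegenerateInputError(
                f"leave-one-out subset omitting index {i} has zero variance"
            )
    dx = x_loo - x_loo.mean(axis=1, keepdims=True)
    dy = y_loo - y_loo.mean(axis=1, keepdims=True)
    r_loo = (dx * dy).sum(axis=1) / np.sqrt(
        (dx * dx).sum(axis=1) * (dy * dy).sum(axis=1)
    )
    # canonical order => bit-identical result under relabeling
    r_loo.sort()
    r_mean = float(r_loo.mean())
    se = float(math.sqrt((n - 1) / n * float(np.sum((r_loo - r_mean) ** 2))))
    return JackknifeEstimate(r_mean=r_mean, se=se, n=n)


def _split_sets(
    reactions: Sequence[ArrheniusReaction],
) -> tuple[list[ArrheniusReaction], list[ArrheniusReaction]]:
    uncat = [r for r in reactions if not r.catalysed]
    cat = [r for r in reactions if r.catalysed]
    by_id = {r.id: r for r in uncat}
    dangling = [r.pair_id for r in cat if r.pair_id not in by_id]
    if dangling:
        raise LinkageError(
            "catalysed records reference unknown uncatalysed ids: "
            + ", ".join(sorted(set(map(str, dangling))))
        )
    return uncat, cat


def cqt_test(
    reactions: Sequence[ArrheniusReaction],
    t_min: float = 0.0,
    t_max: float = 200.0,
    step: float = 1.0,
) -> CqtProfiles:
    """Jackknife correlation of Ea against ln k_non(T) across a °C grid.

    The uncatalysed profile correlates each uncatalysed reaction's own
    Ea with its ln k_non(T). The catalysed profile correlates each
    catalysed reaction's Ea with the ln k_non(T) of its *paired*
    uncatalysed reaction; it therefore never uses the uncatalysed set's
    Ea values. With no catalysed records the catalysed profile is
    ``None``.
    """
    uncat, cat = _split_sets(reactions)
    if len(uncat) < 4:
        raise DegenerateInputError(
            f"need >= 4 uncatalysed reactions, got {len(uncat)}"
        )
    temps = _grid(t_min, t_max, step)
    profiles = {r.id: knon_profile(r, t_min, t_max, step) for r in uncat}
    ea_uncat = np.array([resolve_ea(r) for r in uncat])
    lnk_uncat = np.vstack([profiles[r.id] for r in uncat])  # (n_uncat, n_T)

    uncat_est = [
        jackknife_correlation(ea_uncat, lnk_uncat[:, j]) for j in range(temps.size)
    ]

    cat_est: list[JackknifeEstimate] | None = None
    if cat:
        if len(cat) < 4:
            raise DegenerateInputError(
                f"need >= 4 catalysed reactions (or none), got {len(cat)}"
            )
        ea_cat = np.array([resolve_ea(r) for r in cat])
        lnk_paired = np.vstack([profiles[r.pair_id] for r in cat])
        cat_est = [
            jackknife_correlation(ea_cat, lnk_paired[:, j])
            for j in range(temps.size)
        ]
    return CqtProfiles(temperatures=temps, uncatalysed=uncat_est, catalysed=cat_est)


def summarize_ranges(reactions: Sequence[ArrheniusReaction]) -> dict:
    """Descriptive extrema per set: Ea range, ln k25 range, Q10 range
    (evaluated between 20 and 30°C), and whether any catalysed record
    has a negative barrier lowering ΔEa relative to its pair."""
    if not reactions:
        raise InvalidArgumentError("no reactions supplied")
    uncat, cat = _split_sets(reactions)
    out: dict = {}
    for label, subset in (("uncatalysed", uncat), ("catalysed", cat)):
        if not subset:
            continue
        eas = [resolve_ea(r) for r in subset]
        entry = {
            "n": len(subset),
            "ea_min": min(eas),
            "ea_max": max(eas),
            "q10_min": kinetics.q10_from_ea(min(eas)),
            "q10_max": kinetics.q10_from_ea(max(eas)),
        }
        lnk = [r.ln_k25 for r in subset if r.ln_k25 is not None]
        if lnk:
            entry["ln_k25_min"] = min(lnk)
            entry["ln_k25_max"] = max(lnk)
        out[label] = entry
    if uncat and cat:
        by_id = {r.id: r for r in uncat}
        deltas = [
            resolve_ea(by_id[r.pair_id]) - resolve_ea(r) for r in cat
        ]
        out["delta_ea_min"] = min(deltas)
        out["delta_ea_max"] = max(deltas)
        out["negative_delta_ea"] = any(d < 0 for d in deltas)
    return out
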