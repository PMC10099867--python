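"""Rate-law conversions for temperature-sensitivity analysis.

Two rate models are used side by side:

* the **exponential (Q10) model** for soil respiration,
  ``ln R(T) = ln R0 + b·T`` with temperature in °C, where ``Q10 = exp(10·b)``
  is the factor by which the rate rises over a 10°C interval; and
* the **Arrhenius model** for chemical reactions,
  ``ln k(T) = ln A − Ea/(R·T)`` with absolute temperature, where ``Ea``
  (kJ·mol⁻¹) is the activation energy.

Energies are kJ·mol⁻¹ at every interface; rate constants are handled in
natural-log space throughout so that uncatalysed rates down to ~1e-20 s⁻¹
never underflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import IdenticalResponsesError, InvalidArgumentError

#: Universal gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314

#: Offset between °C and K.
KELVIN_OFFSET = 273.15

#: Seconds in one Julian year.
SECONDS_PER_YEAR = 3.15576e7

#: Default reference temperature for rate constants, K (25°C).
T_REF_DEFAULT = 298.15


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ExponentialResponse:
    """A fitted log-linear temperature response for one incubation.

    Attributes
    ----------
    ln_r0:
        Natural log of the respiration rate at 0°C (log of rate in the
        dataset's rate unit).
    b:
        Slope of ln(rate) against temperature, per °C.
    """

    ln_r0: float
    b: float

    def __post_init__(self) -> None:
        _require_finite("ln_r0", self.ln_r0)
        _require_finite("b", self.b)

    @property
    def q10(self) -> float:
        """Temperature sensitivity ``exp(10·b)``; strictly positive."""
        return q10_from_b(self.b)

    def ln_rate(self, t_celsius: float) -> float:
        """Natural-log rate at temperature ``t_celsius`` (°C)."""
        return self.ln_r0 + self.b * float(t_celsius)


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius description of one first-order reaction.

    Attributes
    ----------
    ea:
        Activation energy, kJ·mol⁻¹ (non-negative).
    ln_k_ref:
        Natural log of the rate constant (s⁻¹) at ``t_ref``.
    t_ref:
        Absolute reference temperature, K. Default 298.15 K (25°C).
    """

    ea: float
    ln_k_ref: float
    t_ref: float = T_REF_DEFAULT

    def __post_init__(self) -> None:
        _require_finite("ea", self.ea)
        _require_finite("ln_k_ref", self.ln_k_ref)
        _require_finite("t_ref", self.t_ref)
        if self.t_ref <= 0:
            raise InvalidArgumentError(f"t_ref must be > 0 K, got {self.t_ref}")
        if self.ea < 0:
            raise InvalidArgumentError(f"ea must be >= 0 kJ/mol, got {self.ea}")


def q10_from_b(b: float) -> float:
    """Q10 implied by the exponential-model slope ``b`` (per °C)."""
    return math.exp(10.0 * _require_finite("b", b))


def b_from_q10(q10: float) -> float:
    """Exponential-model slope (per °C) implied by ``q10``; inverse of
    :func:`q10_from_b`."""
    q10 = _require_finite("q10", q10)
    if q10 <= 0:
        raise InvalidArgumentError(f"q10 must be > 0, got {q10}")
    return math.log(q10) / 10.0


def q10_from_ea(ea: float, t_low: float = 20.0, t_high: float = 30.0) -> float:
    """Q10 of an Arrhenius reaction evaluated between two temperatures.

    Parameters
    ----------
    ea:
        Activation energy, kJ·mol⁻¹.
    t_low, t_high:
        Temperature interval in °C; default (20, 30), the conventional
        interval for quoting Q10 of chemical reactions.

    Returns
    -------
    float
        ``[exp((Ea/R)·(1/T_low − 1/T_high))]^(10/(t_high−t_low))`` with
        temperatures in K; with the default 10°C gap the outer exponent is 1.
    """
    ea = _require_finite("ea", ea)
    t_low = _require_finite("t_low", t_low)
    t_high = _require_finite("t_high", t_high)
    if t_high <= t_low:
        raise InvalidArgumentError(f"t_high ({t_high}) must exceed t_low ({t_low})")
    if t_low <= -KELVIN_OFFSET:
        raise InvalidArgumentError("temperatures must exceed absolute zero")
    tl_k = t_low + KELVIN_OFFSET
    th_k = t_high + KELVIN_OFFSET
    log_ratio = (ea * 1000.0 / GAS_CONSTANT) * (1.0 / tl_k - 1.0 / th_k)
    return math.exp(log_ratio * 10.0 / (t_high - t_low))


def ea_from_q10(q10: float, t_low: float = 20.0, t_high: float = 30.0) -> float:
    """Activation energy (kJ·mol⁻¹) implied by a Q10 between two
    temperatures; exact inverse of :func:`q10_from_ea`."""
    q10 = _require_finite("q10", q10)
    if q10 <= 0:
        raise InvalidArgumentError(f"q10 must be > 0, got {q10}")
    if t_high <= t_low:
        raise InvalidArgumentError(f"t_high ({t_high}) must exceed t_low ({t_low})")
    tl_k = t_low + KELVIN_OFFSET
    th_k = t_high + KELVIN_OFFSET
    log_ratio = math.log(q10) * (t_high - t_low) / 10.0
    return log_ratio * GAS_CONSTANT / 1000.0 / (1.0 / tl_k - 1.0 / th_k)


def ea_from_enthalpy(dh_kj_mol: float, t: float) -> float:
    """Convert an Eyring enthalpy of activation ΔH‡ to an Arrhenius Ea.

    For a reaction in solution ``Ea = ΔH‡ + R·T``; both energies in
    kJ·mol⁻¹, ``t`` in K.
    """
    dh_kj_mol = _require_finite("dh_kj_mol", dh_kj_mol)
    t = _require_finite("t", t)
    if t <= 0:
        raise InvalidArgumentError(f"t must be > 0 K, got {t}")
    return dh_kj_mol + GAS_CONSTANT * 1e-3 * t


def arrhenius_extrapolate(p: ArrheniusParams, t: float) -> float:
    """Natural-log rate constant at absolute temperature ``t`` (K).

    Linear extrapolation on the Arrhenius plot anchored at ``p.t_ref``:
    ``ln k(t) = ln k_ref + (Ea/R)·(1/t_ref − 1/t)``. Equals ``ln_k_ref``
    exactly at ``t = t_ref``.
    """
    t = _require_finite("t", t)
    if t <= 0:
        raise InvalidArgumentError(f"t must be > 0 K, got {t}")
    return p.ln_k_ref + (p.ea * 1000.0 / GAS_CONSTANT) * (1.0 / p.t_ref - 1.0 / t)


def half_life(k: float, unit: str = "seconds") -> float:
    """First-order half-life ``ln 2 / k`` for a rate constant in s⁻¹.

    ``unit`` selects ``"seconds"`` or ``"years"`` (Julian year,
    3.15576e7 s).
    """
    k = _require_finite("k", k)
    if k <= 0:
        raise InvalidArgumentError(f"rate constant must be > 0, got {k}")
    t_seconds = math.log(2.0) / k
    if unit == "seconds":
        return t_seconds
    if unit == "years":
        return t_seconds / SECONDS_PER_YEAR
    raise InvalidArgumentError(f"unit must be 'seconds' or 'years', got {unit!r}")


def crossover_temperature(
    a: ExponentialResponse, c: ExponentialResponse
) -> float | None:
    """Temperature (°C) where two log-linear responses have equal ln rate.

    Returns ``None`` for parallel but distinct curves (they never cross)
    and raises :class:`IdenticalResponsesError` when the curves coincide
    everywhere, since no single cross-over temperature exists.
    """
    if a.b == c.b:
        if a.ln_r0 == c.ln_r0:
            raise IdenticalResponsesError(
                "responses are identical: equal at every temperature"
            )
        return None
    return (a.ln_r0 - c.ln_r0) / (c.b - a.b)


def rate_enhancement(ln_kcat: float, ln_knon: float) -> float:
    """Fold rate enhancement ``kcat/knon`` from natural-log rate constants."""
    ln_kcat = _require_finite("ln_kcat", ln_kcat)
    ln_knon = _require_finite("ln_knon", ln_knon)
    return math.exp(ln_kcat - ln_knon)


def delta_ea(ea_non: float, ea_cat: float) -> float:
    """Barrier lowering ``Ea_non − Ea_cat`` (kJ·mol⁻¹) achieved by an enzyme.

    A negative result means the catalysed reaction has the *higher*
    barrier; a warning is emitted since that usually indicates a data or
    pairing problem.
    """
    ea_non = _require_finite("ea_non", ea_non)
    ea_cat = _require_finite("ea_cat", ea_cat)
    diff = ea_non - ea_cat
    if diff < 0:
        warnings.warn(
            f"negative ΔEa ({diff:.3g} kJ/mol): catalysed barrier exceeds "
            "uncatalysed barrier",
            stacklevel=2,
        )
    return diff
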