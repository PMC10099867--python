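"""Synthetic datasets with the statistical structure the analyses assume.

Three generators:

* :func:`generate_incubations` — a population of (b, ln R0) pairs drawn
  from a bivariate normal with a tunable correlation ``rho``, emulating a
  compilation of soil-incubation temperature responses. The defaults give
  Q10 values centred near 2.5 with a negative b–ln R0 association, so the
  downstream correlation sweep exhibits the reference-temperature sign
  flip inside the 0–60°C window.
* :func:`simulate_noise_artefact` — repeated noisy measurements of a
  *single* true response, each refit by OLS, demonstrating that random
  measurement error alone induces a negative correlation between fitted
  Q10 and fitted ln R0 (slope–intercept error compensation: the OLS
  slope–intercept covariance is −T̄·var(slope), negative whenever the
  measurement temperatures have a positive mean).
* :func:`generate_reactions` — uncatalysed reactions with Ea drawn
  uniformly and a shared-to-noisy pre-exponential factor, so ln k25 is
  negatively tied to Ea (exactly collinear when ``ln_a_sd = 0`` — the
  positive control), plus catalysed partners whose Ea is drawn
  independently of everything else (the null case the CQT test should
  report as "no correlation").

All generators are pure functions of their configuration: the same seed
yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .incubation import IncubationRecord, pearson_correlation
from .kinetics import (
    ExponentialResponse,
    GAS_CONSTANT,
    T_REF_DEFAULT,
)
from .reactions import ArrheniusReaction

__all__ = [
    "IncubationGenConfig",
    "NoiseSimConfig",
    "ReactionGenConfig",
    "EA_NON_PRESET_A",
    "EA_NON_PRESET_B",
    "generate_incubations",
    "fit_exponential_response",
    "simulate_noise_artefact",
    "generate_reactions",
]

#: Uncatalysed Ea range (kJ/mol) matching the full reaction compilation.
EA_NON_PRESET_A = (35.0, 199.0)
#: Uncatalysed Ea range (kJ/mol) matching the enzyme-paired subset.
EA_NON_PRESET_B = (90.0, 200.0)


@dataclass(frozen=True)
class IncubationGenConfig:
    """Bivariate-normal population of incubation responses.

    ``(b, ln_r0)`` pairs are drawn with the configured marginal moments
    and correlation ``rho``; Q10 is derived as ``exp(10·b)``. Defaults:
    113 incubations (a typical compilation size), mean b = 0.09 per °C
    (Q10 ≈ 2.5), and a strong negative slope–intercept association.
    """

    n: int = 113
    mean_b: float = 0.09
    sd_b: float = 0.02
    mean_lnr0: float = 0.0
    sd_lnr0: float = 1.0
    rho: float = -0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ConfigError(f"n must be >= 3, got {self.n}")
        if self.sd_b < 0 or self.sd_lnr0 < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not -1 < self.rho < 1:
            raise ConfigError(f"rho must lie in (-1, 1), got {self.rho}")
        for name in ("mean_b", "sd_b", "mean_lnr0", "sd_lnr0", "rho"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


@dataclass(frozen=True)
class NoiseSimConfig:
    """Noisy re-measurement of a single true exponential response.

    ``temps`` is the measurement grid in °C (default 4–28°C every 4°C, a
    common laboratory incubation range); ``noise_sd`` is the standard
    deviation of additive Gaussian noise on ln rate (multiplicative
    lognormal noise on the rate itself).
    """

    true_q10: float = 2.5
    true_lnr0: float = 0.0
    temps: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0)
    noise_sd: float = 0.2
    n_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_q10 <= 0:
            raise ConfigError(f"true_q10 must be > 0, got {self.true_q10}")
        if len(self.temps) < 3:
            raise ConfigError("need >= 3 measurement temperatures")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_samples < 3:
            raise ConfigError(f"n_samples must be >= 3, got {self.n_samples}")


@dataclass(frozen=True)
class ReactionGenConfig:
    """Population of uncatalysed reactions plus catalysed partners.

    Uncatalysed: ``Ea ~ Uniform(ea_non_range)``, pre-exponential
    ``ln A ~ Normal(ln_a_mean, ln_a_sd)`` (s⁻¹), and
    ``ln k25 = ln A − Ea/(R·298.15 K)``. With the default ln A centred on
    ln(1e10 s⁻¹), the generated ln k25 values cover the many-orders-of-
    magnitude span characteristic of uncatalysed biological reactions
    (~1e-3 down to ~1e-20 s⁻¹). Catalysed: Ea drawn independently from
    ``ea_cat_range`` and linked injectively to distinct uncatalysed
    records.
    """

    n_non: int = 56
    n_cat: int = 21
    ln_a_mean: float = math.log(1e10)
    ln_a_sd: float = 2.0
    ea_non_range: tuple[float, float] = EA_NON_PRESET_A
    ea_cat_range: tuple[float, float] = (40.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_non < 4:
            raise ConfigError(f"n_non must be >= 4, got {self.n_non}")
        if self.n_cat < 0:
            raise ConfigError(f"n_cat must be >= 0, got {self.n_cat}")
        if self.n_cat > self.n_non:
            raise ConfigError(
                f"n_cat ({self.n_cat}) may not exceed n_non ({self.n_non}): "
                "pairing must be injective"
            )
        for rng_name in ("ea_non_range", "ea_cat_range"):
            lo, hi = getattr(self, rng_name)
            if not lo <= hi:
                raise ConfigError(f"{rng_name} must be ordered, got ({lo}, {hi})")
        if self.ln_a_sd < 0:
            raise ConfigError(f"ln_a_sd must be >= 0, got {self.ln_a_sd}")


def generate_incubations(cfg: IncubationGenConfig) -> list[IncubationRecord]:
    """Draw ``cfg.n`` incubation records from the configured bivariate normal."""
    rng = np.random.default_rng(cfg.seed)
    # explicit Cholesky factor of the 2x2 covariance; valid even when a
    # standard deviation is zero (degenerate population)
    z = rng.standard_normal((cfg.n, 2))
    b = cfg.mean_b + cfg.sd_b * z[:, 0]
    lnr0 = cfg.mean_lnr0 + cfg.sd_lnr0 * (
        cfg.rho * z[:, 0] + math.sqrt(1.0 - cfg.rho**2) * z[:, 1]
    )
    return [
        IncubationRecord(
            id=f"syn{i:04d}",
            source="synthetic",
            q10=math.exp(10.0 * b[i]),
            ln_r0=float(lnr0[i]),
        )
        for i in range(cfg.n)
    ]


def fit_exponential_response(
    temps: Sequence[float], ln_rates: Sequence[float]
) -> ExponentialResponse:
    """Ordinary least-squares fit of ln rate on temperature (°C).

    Returns the fitted intercept (ln R0, the log rate at 0°C) and slope b.
    """
    t = np.asarray(temps, dtype=float)
    y = np.asarray(ln_rates, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 2:
        raise DegenerateInputError("need >= 2 (temperature, ln rate) pairs")
    if np.ptp(t) == 0:
        raise DegenerateInputError("all temperatures equal: slope unidentifiable")
    dt = t - t.mean()
    b = float(np.dot(dt, y - y.mean()) / np.dot(dt, dt))
    ln_r0 = float(y.mean() - b * t.mean())
    return ExponentialResponse(ln_r0=ln_r0, b=b)


def simulate_noise_artefact(
    cfg: NoiseSimConfig,
) -> tuple[list[IncubationRecord], dict]:
    """Fit noisy re-measurements of one true curve; summarise the induced
    slope–intercept correlation.

    Returns the fitted records and a summary dict with keys ``r`` and
    ``p`` (Pearson correlation between fitted Q10 and fitted ln R0 with
    its two-sided p-value) plus ``degenerate`` (True when ``noise_sd=0``
    makes every fit identical, leaving the correlation undefined).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.temps, dtype=float)
    true_b = math.log(cfg.true_q10) / 10.0
    true_line = cfg.true_lnr0 + true_b * t
    records = []
    for i in range(cfg.n_samples):
        noisy = true_line + rng.normal(0.0, cfg.noise_sd, size=t.size)
        fit = fit_exponential_response(t, noisy)
        records.append(
            IncubationRecord(
                id=f"noise{i:04d}",
                source="noise-sim",
                q10=fit.q10,
                ln_r0=fit.ln_r0,
            )
        )
    q10s = [r.q10 for r in records]
    lnr0s = [r.ln_r0 for r in records]
    summary: dict = {
        "n_samples": cfg.n_samples,
        "noise_sd": cfg.noise_sd,
        "mean_temp": float(t.mean()),
    }
    try:
        r, p = pearson_correlation(q10s, lnr0s)
    except DegenerateInputError:
        summary.update(r=float("nan"), p=float("nan"), degenerate=True)
    else:
        summary.update(r=r, p=p, degenerate=False)
    return records, summary


def generate_reactions(cfg: ReactionGenConfig) -> list[ArrheniusReaction]:
    """Draw an uncatalysed reaction set plus independently-parameterised
    catalysed partners; see :class:`ReactionGenConfig` for the model."""
    rng = np.random.default_rng(cfg.seed)
    ea_non = rng.uniform(*cfg.ea_non_range, size=cfg.n_non)
    ln_a = cfg.ln_a_mean + cfg.ln_a_sd * rng.standard_normal(cfg.n_non)
    ln_k25 = ln_a - ea_non * 1000.0 / (GAS_CONSTANT * T_REF_DEFAULT)
    reactions = [
        ArrheniusReaction(
            id=f"non{i:04d}",
            name=f"uncatalysed reaction {i}",
            catalysed=False,
            ea=float(ea_non[i]),
            ln_k25=float(ln_k25[i]),
        )
        for i in range(cfg.n_non)
    ]
    if cfg.n_cat:
        ea_cat = rng.uniform(*cfg.ea_cat_range, size=cfg.n_cat)
        partners = rng.choice(cfg.n_non, size=cfg.n_cat, replace=False)
        reactions.extend(
            ArrheniusReaction(
                id=f"cat{j:04d}",
                name=f"catalysed counterpart of non{int(partners[j]):04d}",
                catalysed=True,
                pair_id=f"non{int(partners[j]):04d}",
                ea=float(ea_cat[j]),
            )
            for j in range(cfg.n_cat)
        )
    return reactions
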