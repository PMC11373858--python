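"""Closed-form components of the Maintenance-Growth Model (MGM).

The MGM describes individual growth under ad libitum feeding as an energy
balance: ingested energy ``S`` is assimilated with efficiency ``e`` and spent
on feeding costs ``R_F(S)``, maintenance ``R_M(W)`` and growth, with growth
split between energy bound in new biomass (``E_M`` per mg) and synthesis
overhead lost as heat (``E_S`` per mg)::

    dW/dt = (e*S - R_F(S) - R_M(W)) / (E_M + E_S)

Component specifications:

* ``S(W)`` — a power allometry ``alpha*W**beta`` until imago emergence
  (``W <= W_mat``) and, after maturity, the branch whose mass-derivative is
  ``k*W**(beta-1)*(W_star - W)`` so that ingestion peaks at ``W = W_star``
  and declines beyond it.
* ``R_F(S)`` — a continuous "hockey-stick": slope ``kF1`` below the
  breakpoint ``S1``, steeper slope ``kF2`` above it.
* ``R_M(W)`` — basal maintenance linear in mass (coefficient ``gamma_B``,
  or ``gamma_BS`` / ``gamma_BR`` for female somatic / reproductive tissue),
  plus a negotiable share that grows linearly with mass (``a_N``), giving
  superlinear total maintenance ``gamma*W / (1 - a_N*W)``.

Units are fixed package-wide: mass in mg fresh weight, energy in J, time in
days.  All operations accept scalar or ndarray mass arguments.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "MGMParams",
    "GSGMParams",
    "MaintenanceCost",
    "ParameterError",
    "ValidityDomainError",
    "ingestion_rate",
    "feeding_cost",
    "maintenance_cost",
    "growth_rate_full",
    "growth_rate_resting_form",
    "growth_rate_compact",
    "gsgm_rate",
    "PARAM_UNITS",
]


class ParameterError(ValueError):
    """A parameter set violates the model's structural constraints."""


class ValidityDomainError(ValueError):
    """Evaluation outside the model's validity domain (``a_N*W >= 1``).

    The negotiable-maintenance term ``gamma*W/(1 - a_N*W)`` has a pole at
    ``W = 1/a_N``; masses at or beyond the pole signal a structurally
    invalid trial, not a numerical accident, so they raise instead of
    returning infinities.
    """


PARAM_UNITS = {
    "sex": "categorical {male, female}",
    "e": "dimensionless (J assimilated per J ingested)",
    "E_M": "J/mg (biomass energy density)",
    "E_S": "J/mg (specific growth overhead)",
    "alpha": "J/day/mg^beta (juvenile ingestion normalization)",
    "beta": "dimensionless (juvenile ingestion exponent)",
    "k": "J/day/mg^(beta+1) (adult ingestion shape constant)",
    "W_star": "mg (mass at peak adult ingestion)",
    "W_mat": "mg (mass at imago emergence)",
    "S1": "J/day (feeding-cost breakpoint)",
    "kF1": "dimensionless (feeding-cost slope below S1)",
    "kF2": "dimensionless (feeding-cost slope above S1)",
    "gamma_B": "J/day/mg (male basal maintenance coefficient)",
    "gamma_BS": "J/day/mg (female somatic basal maintenance)",
    "gamma_BR": "J/day/mg (female reproductive basal maintenance)",
    "a_N": "1/mg (negotiable-allocation proportionality)",
    "a_R": "J/day/mg^b_R (resting-metabolism normalization)",
    "b_R": "dimensionless (resting-metabolism exponent)",
    "W_0": "mg (birth mass, initial condition)",
    "phi": "dimensionless (relative food acquirement; fixed at 1)",
}


@dataclass(frozen=True)
class MGMParams:
    """Full parameter set of the ad libitum MGM for one sex.

    Male maintenance uses ``gamma_B``; females use ``gamma_BS`` before and
    ``gamma_BS``/``gamma_BR`` after imago emergence.  ``a_R`` and ``b_R``
    parameterize the resting-metabolic-rate allometry ``R_R ~ a_R*W**b_R``
    used by the resting-form growth equation.
    """

    sex: str
    e: float
    E_M: float
    E_S: float
    alpha: float
    beta: float
    k: float
    W_star: float
    W_mat: float
    S1: float
    kF1: float
    kF2: float
    a_N: float
    a_R: float
    b_R: float
    W_0: float
    gamma_B: float | None = None
    gamma_BS: float | None = None
    gamma_BR: float | None = None
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ParameterError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0.0 < self.e <= 1.0):
            raise ParameterError(f"assimilation efficiency e must be in (0, 1], got {self.e}")
        if self.E_M <= 0:
            raise ParameterError("biomass energy density E_M must be positive")
        if self.E_S < 0:
            raise ParameterError("growth overhead E_S must be nonnegative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("ingestion allometry requires alpha > 0 and beta > 0")
        if self.k < 0:
            raise ParameterError("adult ingestion constant k must be nonnegative")
        if self.W_0 <= 0 or self.W_mat <= 0 or not self.W_0 < self.W_mat:
            raise ParameterError("need 0 < W_0 < W_mat")
        if self.S1 < 0:
            raise ParameterError("feeding-cost breakpoint S1 must be nonnegative")
        if not (0.0 <= self.kF1 <= self.kF2):
            raise ParameterError("feeding-cost slopes require 0 <= kF1 <= kF2")
        if self.a_N < 0:
            raise ParameterError("a_N must be nonnegative")
        if self.a_R < 0 or self.b_R < 0:
            raise ParameterError("resting allometry requires a_R, b_R >= 0")
        if self.phi != 1.0:
            raise ParameterError(
                "only ad libitum growth is modelled here: phi must equal 1"
            )
        if self.sex == "male":
            if self.gamma_B is None or self.gamma_B <= 0:
                raise ParameterError("males require gamma_B > 0")
        else:
            if self.gamma_BS is None or self.gamma_BS <= 0:
                raise ParameterError("females require gamma_BS > 0")
            if self.gamma_BR is None or self.gamma_BR <= 0:
                raise ParameterError("females require gamma_BR > 0")
        if self.a_N > 0 and self.a_N * self.W_mat >= 1.0:
            raise ParameterError(
                "maturity mass lies beyond the maintenance singularity (a_N*W_mat >= 1)"
            )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, mapping: dict) -> "MGMParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known - {"units"}
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        payload = {k: v for k, v in mapping.items() if k != "units"}
        return cls(**payload)

    def to_yaml(self) -> str:
        """Serialize to a flat YAML mapping with unit annotations."""
        lines = ["# MGM parameter set (mass mg, energy J, time days)"]
        for key, value in self.to_dict().items():
            unit = PARAM_UNITS.get(key, "")
            lines.append(f"{key}: {value!r}  # {unit}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_yaml(cls, text: str) -> "MGMParams":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **changes) -> "MGMParams":
        return dataclasses.replace(self, **changes)

    @property
    def gamma_juvenile(self) -> float:
        """Basal maintenance coefficient applicable before imago emergence."""
        return self.gamma_B if self.sex == "male" else self.gamma_BS  # type: ignore[return-value]


@dataclass(frozen=True)
class GSGMParams:
    """Generalized Standard Growth Model ``dW/dt = a*W**b - c*W**d``.

    The family nests von Bertalanffy / anabolism-catabolism models, standard
    DEB and ontogenetic growth models via the exponent pair ``(b, d)``.
    A finite asymptote requires ``b < d``; ``d > 1`` lies outside the
    standard family and triggers a warning.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ParameterError("GSGM requires a > 0 and c > 0")
        if not self.b < self.d:
            raise ParameterError(
                "GSGM requires b < d for a finite asymptote (b == d is degenerate)"
            )
        if self.b <= 0:
            raise ParameterError("GSGM requires b > 0")
        if self.d > 1:
            warnings.warn(
                "GSGM with d > 1 lies outside the standard model family "
                "(AnaCat/DEB/OGM all use d <= 1)",
                stacklevel=2,
            )

    @property
    def asymptotic_mass(self) -> float:
        return (self.a / self.c) ** (1.0 / (self.d - self.b))


class MaintenanceCost(NamedTuple):
    """Total, basal and negotiable maintenance costs (J/day)."""

    R_M: np.ndarray | float
    R_MB: np.ndarray | float
    R_MN: np.ndarray | float


def _check_mass(W) -> np.ndarray | float:
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("body mass W must be positive")
    return W if W.ndim else float(W)


def ingestion_rate(W, p: MGMParams):
    """Ad libitum ingestion rate S(W) in J/day.

    Power allometry ``alpha*W**beta`` up to maturity; beyond it the branch
    with derivative ``k*W**(beta-1)*(W_star - W)``, i.e. ingestion keeps
    rising until ``W_star`` and declines for larger masses.  Continuous at
    ``W = W_mat``; masses exactly at the break use the juvenile branch
    (both branches agree there).
    """
    W = _check_mass(W)
    b, Wm = p.beta, p.W_mat
    juv = p.alpha * np.power(W, b)
    S_mat = p.alpha * Wm**b
    adult = S_mat + p.k * (
        p.W_star * (np.power(W, b) - Wm**b) / b
        - (np.power(W, 1.0 + b) - Wm ** (1.0 + b)) / (1.0 + b)
    )
    return np.where(W <= Wm, juv, adult) if np.ndim(W) else (juv if W <= Wm else adult)


def ingestion_rate_derivative(W, p: MGMParams):
    """dS/dW: ``alpha*beta*W**(beta-1)`` (juvenile) or ``k*W**(beta-1)*(W_star-W)``."""
    W = _check_mass(W)
    juv = p.alpha * p.beta * np.power(W, p.beta - 1.0)
    adult = p.k * np.power(W, p.beta - 1.0) * (p.W_star - W)
    return np.where(W <= p.W_mat, juv, adult) if np.ndim(W) else (juv if W <= p.W_mat else adult)


def feeding_cost(S, p: MGMParams):
    """Hockey-stick feeding cost R_F(S): kF1*S below S1, then slope kF2."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("ingestion rate S must be nonnegative")
    low = p.kF1 * S
    high = p.kF1 * p.S1 + p.kF2 * (S - p.S1)
    out = np.where(S <= p.S1, low, high)
    return out if S.ndim else float(out)


def _negotiable_term(gamma: float, mass, a_N: float):
    """gamma*m/(1 - a_N*m) with a typed error at the pole."""
    mass = np.asarray(mass, dtype=float)
    if np.any(a_N * mass >= 1.0):
        raise ValidityDomainError(
            f"a_N*mass >= 1 (mass up to {np.max(mass):.6g} mg, a_N={a_N:.6g}/mg): "
            "maintenance singularity reached"
        )
    return gamma * mass / (1.0 - a_N * mass)


def maintenance_cost(W, p: MGMParams) -> MaintenanceCost:
    """Maintenance costs R_M with its basal (R_MB) and negotiable (R_MN) parts.

    Males: ``R_M = gamma_B*W/(1 - a_N*W)`` at any mass.  Females switch the
    negotiable allocation from somatic to reproductive tissue at imago
    emergence; the post-maturity branch is continuous at ``W = W_mat``.
    The basal part is the numerator-linear term (``gamma * mass``), so the
    negotiable share satisfies ``R_MN/R_M = a_N*mass`` by construction.
    """
    W = _check_mass(W)
    scalar = np.ndim(W) == 0
    Wa = np.atleast_1d(np.asarray(W, dtype=float))
    if p.sex == "male":
        R_M = _negotiable_term(p.gamma_B, Wa, p.a_N)
        R_MB = p.gamma_B * Wa
    else:
        juv = Wa <= p.W_mat
        R_M = np.empty_like(Wa)
        R_MB = np.empty_like(Wa)
        if np.any(juv):
            R_M[juv] = _negotiable_term(p.gamma_BS, Wa[juv], p.a_N)
            R_MB[juv] = p.gamma_BS * Wa[juv]
        if np.any(~juv):
            Wr = Wa[~juv] - p.W_mat  # reproductive mass
            somatic = _negotiable_term(p.gamma_BS, p.W_mat, p.a_N)
            R_M[~juv] = somatic + _negotiable_term(p.gamma_BR, Wr, p.a_N)
            R_MB[~juv] = p.gamma_BS * p.W_mat + p.gamma_BR * Wr
    R_MN = R_M - R_MB
    if scalar:
        return MaintenanceCost(float(R_M[0]), float(R_MB[0]), float(R_MN[0]))
    return MaintenanceCost(R_M, R_MB, R_MN)


def growth_rate_full(W, p: MGMParams):
    """Energy-balance growth rate (mg/day): ``(e*S - R_F - R_M)/(E_M + E_S)``.

    May be negative when costs exceed assimilation (mass loss).
    """
    S = ingestion_rate(W, p)
    R_F = feeding_cost(S, p)
    R_M = maintenance_cost(W, p).R_M
    return (p.e * S - R_F - R_M) / (p.E_M + p.E_S)


def growth_rate_resting_form(W, p: MGMParams):
    """Growth rate from the resting-metabolism decomposition.

    Resting metabolic rate ``R_R = R_G + R_M`` approximated by the allometry
    ``a_R*W**b_R`` gives ``dW/dt = (a_R*W**b_R - R_M(W)) / E_S``.  This form
    avoids the ingestion and feeding-cost parameters entirely, which is what
    makes it usable for inverse calibration of {E_S, gamma, a_N}.
    """
    if p.E_S <= 0:
        raise ParameterError("resting-form growth rate requires E_S > 0")
    W = _check_mass(W)
    R_M = maintenance_cost(W, p).R_M
    return (p.a_R * np.power(W, p.b_R) - R_M) / p.E_S


def growth_rate_compact(W, a: float, beta: float, c: float, a_N: float):
    """Compact four-effective-parameter MGM: ``a*W**beta - c*W/(1 - a_N*W)``.

    Equals the full energy balance when ingestion is a single allometry,
    feeding cost a single slope kF and maintenance sex-undifferentiated,
    under the fusion ``a = (e - kF)*alpha/(E_M + E_S)``,
    ``c = gamma_B/(E_M + E_S)``.  With ``a_N = 0`` it reduces to a GSGM
    member with ``d = 1``.
    """
    if a <= 0 or c <= 0:
        raise ParameterError("compact form requires a > 0 and c > 0")
    if a_N < 0:
        raise ParameterError("a_N must be nonnegative")
    W = _check_mass(W)
    return a * np.power(W, beta) - _negotiable_term(c, W, a_N)


def gsgm_rate(W, g: GSGMParams):
    """GSGM growth rate ``a*W**b - c*W**d`` (mg/day)."""
    W = _check_mass(W)
    return g.a * np.power(W, g.b) - g.c * np.power(W, g.d)
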