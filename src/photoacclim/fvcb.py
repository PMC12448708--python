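"""Biochemical model of C3 photosynthesis and short-term thermal-response forms.

The Farquhar-von Caemmerer-Berry (FvCB) model describes light-saturated net CO2
assimilation (``A_net``, umol CO2 m-2 s-1) as the minimum of a Rubisco-limited
rate ``A_c`` and an RuBP-regeneration-limited rate ``A_j``::

    A_c = Vcmax (Ci - Gamma*) / (Ci + Kc (1 + O/Ko)) - R_L
    A_j = J/4  (Ci - Gamma*) / (Ci + 2 Gamma*)       - R_L

with the electron transport rate ``J`` given by the lower root of the
non-rectangular hyperbola ``theta J^2 - J (alpha Q + Jmax) + alpha Q Jmax = 0``.
Triose-phosphate-utilisation limitation is deliberately excluded.

Kinetic constants (Kc, Ko, Gamma*, R_L) follow a simple Arrhenius temperature
dependence around 25 degC.  Process capacities (Vcmax, Jmax) follow a *peaked*
Arrhenius function with a fixed deactivation energy, and the growth-CO2
operating point of A_net follows a quadratic in leaf temperature; both
thermal-response forms live here as pure functions.

All concentrations are mole fractions in umol mol-1, rates in umol CO2 m-2 s-1,
activation energies in J mol-1.  Quadratic thermal responses operate in degC;
peaked-Arrhenius thermal responses operate in Kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "T0_C",
    "TREF_K",
    "O2_DEFAULT",
    "HD_DEFAULT",
    "KineticsSet",
    "AdjustedKinetics",
    "PeakedArrheniusParams",
    "QuadraticParams",
    "LightParams",
    "InvalidArgumentError",
    "NoOptimumError",
    "load_kinetics",
    "available_kinetics",
    "arrhenius_adjust",
    "peaked_arrhenius",
    "electron_transport",
    "fvcb_ac",
    "fvcb_aj",
    "fvcb_anet",
    "quadratic_agrowth",
    "topt_from_quadratic",
]

R_GAS = 8.314  # universal gas constant, J mol-1 K-1
T0_C = 273.15  # 0 degC in Kelvin
TREF_K = 298.15  # 25 degC reference temperature, K
O2_DEFAULT = 210_000.0  # atmospheric O2 mole fraction, umol mol-1 (21%)
HD_DEFAULT = 200_000.0  # deactivation energy held fixed in peaked fits, J mol-1


class InvalidArgumentError(ValueError):
    """A physically or numerically inadmissible argument was supplied."""


class NoOptimumError(ValueError):
    """A quadratic thermal response with a >= 0 has no interior maximum."""


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise InvalidArgumentError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


class AdjustedKinetics(NamedTuple):
    """Kinetic constants evaluated at one leaf temperature."""

    kc: float
    ko: float
    gammastar: float
    rl: float | None  # None when R_L is to be estimated from the curve fit


@dataclass(frozen=True)
class KineticsSet:
    """Rubisco kinetic constants at 25 degC plus Arrhenius activation energies.

    ``rl25`` may be None, meaning respiration in the light is estimated
    jointly with Vcmax/Jmax during curve fitting rather than fixed from a
    species preset.  Ko and O share the same umol mol-1 convention.
    """

    name: str
    kc25: float
    ko25: float
    gammastar25: float
    rl25: float | None
    ea_kc: float
    ea_ko: float
    ea_gammastar: float
    ea_rl: float

    def __post_init__(self) -> None:
        for field in ("kc25", "ko25", "gammastar25"):
            if not getattr(self, field) > 0:
                raise InvalidArgumentError(f"{field} must be > 0")
        if self.rl25 is not None and self.rl25 < 0:
            raise InvalidArgumentError("rl25 must be >= 0 or None")
        for field in ("ea_kc", "ea_ko", "ea_gammastar", "ea_rl"):
            if getattr(self, field) < 0:
                raise InvalidArgumentError(f"{field} must be >= 0")

    def at_leaf_temperature(self, tleaf_c: float) -> AdjustedKinetics:
        """Arrhenius-adjust Kc, Ko, Gamma* (and R_L if fixed) to ``tleaf_c``."""
        rl = (
            arrhenius_adjust(self.rl25, self.ea_rl, tleaf_c)
            if self.rl25 is not None
            else None
        )
        return AdjustedKinetics(
            kc=arrhenius_adjust(self.kc25, self.ea_kc, tleaf_c),
            ko=arrhenius_adjust(self.ko25, self.ea_ko, tleaf_c),
            gammastar=arrhenius_adjust(self.gammastar25, self.ea_gammastar, tleaf_c),
            rl=rl,
        )

    def with_rl(self, rl25: float | None) -> "KineticsSet":
        return replace(self, rl25=rl25)


@dataclass(frozen=True)
class PeakedArrheniusParams:
    """Parameters of the peaked Arrhenius thermal response (temperatures in K)."""

    kopt: float  # process rate at the thermal optimum, umol CO2 m-2 s-1
    topt: float  # thermal optimum, K
    ea: float  # activation energy, J mol-1
    hd: float = 200_000.0  # deactivation energy, J mol-1 (held fixed in fits)

    def __post_init__(self) -> None:
        if not self.kopt > 0:
            raise InvalidArgumentError("kopt must be > 0")
        if not 0 < self.ea < self.hd:
            raise InvalidArgumentError(
                f"require 0 < ea < hd, got ea={self.ea}, hd={self.hd}"
            )

    @property
    def topt_c(self) -> float:
        return self.topt - T0_C


@dataclass(frozen=True)
class QuadraticParams:
    """Coefficients of the quadratic A_growth(T_l) = a T_l^2 + b T_l + c (degC)."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class LightParams:
    """Electron-transport light model: curvature, quantum yield, and PPFD.

    theta and alpha are dimensionless curve constants (mol electrons mol-1
    photons) held fixed at 0.85 and 0.24; q is the measurement PPFD in
    umol photons m-2 s-1 (saturating-light default 1800).
    """

    theta: float = 0.85
    alpha: float = 0.24
    q: float = 1800.0

    def __post_init__(self) -> None:
        if not 0 <= self.theta < 1:
            raise InvalidArgumentError("theta must be in [0, 1)")
        if not 0 < self.alpha < 0.5:
            raise InvalidArgumentError("alpha must be in (0, 0.5)")
        if self.q < 0:
            raise InvalidArgumentError("q must be >= 0")


# ---------------------------------------------------------------------------
# kinetics presets
# ---------------------------------------------------------------------------


def _presets_table() -> pd.DataFrame:
    with resources.files("photoacclim.data").joinpath("kinetics_presets.csv").open() as fh:
        return pd.read_csv(fh)


def available_kinetics() -> list[str]:
    """Names of the shipped kinetic-constant presets."""
    return sorted(_presets_table()["preset"].unique())


def load_kinetics(name: str = "tobacco") -> KineticsSet:
    """Load a named Rubisco kinetics preset from the packaged data table."""
    table = _presets_table()
    rows = table[table["preset"] == name]
    if rows.empty:
        raise KeyError(
            f"unknown kinetics preset {name!r}; available: {available_kinetics()}"
        )
    values = dict(zip(rows["constant"], rows["value"]))
    rl25 = values.get("rl25")
    if rl25 is not None and math.isnan(rl25):
        rl25 = None
    return KineticsSet(
        name=name,
        kc25=values["kc25"],
        ko25=values["ko25"],
        gammastar25=values["gammastar25"],
        rl25=rl25,
        ea_kc=values["ea_kc"],
        ea_ko=values["ea_ko"],
        ea_gammastar=values["ea_gammastar"],
        ea_rl=values["ea_rl"],
    )


# ---------------------------------------------------------------------------
# temperature responses
# ---------------------------------------------------------------------------


def arrhenius_adjust(k25, ea, tl):
    """Exponential Arrhenius adjustment of a rate from 25 degC to ``tl`` (degC).

    k(T) = k25 * exp(Ea (T_K - 298.15) / (298.15 R T_K)).  Returns k25 exactly
    at tl = 25 and is strictly increasing in tl for ea > 0.
    """
    _require_finite(k25=k25, ea=ea, tl=tl)
    if np.any(np.asarray(k25) <= 0):
        raise InvalidArgumentError("k25 must be > 0")
    tk = np.asarray(tl, dtype=float) + T0_C
    out = k25 * np.exp(ea * (tk - TREF_K) / (TREF_K * R_GAS * tk))
    return float(out) if np.isscalar(tl) or np.ndim(tl) == 0 else out


def peaked_arrhenius(p: PeakedArrheniusParams, tl_k):
    """Peaked Arrhenius rate at leaf temperature ``tl_k`` (Kelvin).

    f(Tl) = kopt * Hd * exp(Ea (Tl - Topt) / (Tl R Topt))
                 / (Hd - Ea (1 - exp(Hd (Tl - Topt) / (Tl R Topt))))

    Equals kopt exactly at Tl = Topt and is strictly below kopt elsewhere.
    """
    _require_finite(tl_k=tl_k)
    tl = np.asarray(tl_k, dtype=float)
    if np.any(tl <= 0):
        raise InvalidArgumentError("tl_k must be > 0 K")
    if p.ea >= p.hd:
        raise InvalidArgumentError("ea must be < hd")
    x = (tl - p.topt) / (tl * R_GAS * p.topt)
    # exp(hd*x) overflows for tl far above topt; the function tends to 0 there.
    with np.errstate(over="ignore"):
        denom = p.hd - p.ea * (1.0 - np.exp(p.hd * x))
        out = p.kopt * p.hd * np.exp(p.ea * x) / denom
    out = np.where(np.isfinite(out), out, 0.0)
    return float(out) if np.ndim(tl_k) == 0 else out


def electron_transport(lp: LightParams, jmax: float):
    """Electron transport rate J: lower root of the non-rectangular hyperbola.

    theta J^2 - J (alpha Q + Jmax) + alpha Q Jmax = 0.  The lower root
    satisfies 0 <= J <= min(alpha Q, Jmax) and tends to Jmax as Q grows.
    For theta = 0 the quadratic degenerates to the rectangular hyperbola
    J = alpha Q Jmax / (alpha Q + Jmax).
    """
    _require_finite(jmax=jmax)
    if not jmax > 0:
        raise InvalidArgumentError("jmax must be > 0")
    aq = lp.alpha * lp.q
    if lp.theta == 0.0:
        return aq * jmax / (aq + jmax) if aq + jmax > 0 else 0.0
    b = aq + jmax
    disc = b * b - 4.0 * lp.theta * aq * jmax
    if disc < 0:
        if disc > -1e-9 * b * b:  # numerically zero discriminant
            disc = 0.0
        else:
            raise InvalidArgumentError("negative discriminant in electron transport")
    return (b - math.sqrt(disc)) / (2.0 * lp.theta)


# ---------------------------------------------------------------------------
# FvCB assimilation rates
# ---------------------------------------------------------------------------


def fvcb_ac(vcmax, ci, o, kin: AdjustedKinetics, rl):
    """Rubisco-limited net assimilation A_c at the given Ci (umol mol-1)."""
    _require_finite(vcmax=vcmax, ci=ci, o=o, rl=rl)
    if np.any(np.asarray(vcmax) < 0):
        raise InvalidArgumentError("vcmax must be >= 0")
    if not o > 0:
        raise InvalidArgumentError("o must be > 0")
    ci = np.asarray(ci, dtype=float)
    km = kin.kc * (1.0 + o / kin.ko)
    out = vcmax * (ci - kin.gammastar) / (ci + km) - rl
    return float(out) if np.ndim(out) == 0 else out


def fvcb_aj(j, ci, gammastar, rl):
    """RuBP-regeneration-limited net assimilation A_j at the given Ci."""
    _require_finite(j=j, ci=ci, gammastar=gammastar, rl=rl)
    if np.any(np.asarray(j) < 0):
        raise InvalidArgumentError("j must be >= 0")
    ci = np.asarray(ci, dtype=float)
    out = (j / 4.0) * (ci - gammastar) / (ci + 2.0 * gammastar) - rl
    return float(out) if np.ndim(out) == 0 else out


def fvcb_anet(vcmax, jmax, ci, o, kin: AdjustedKinetics, rl, lp: LightParams):
    """Net assimilation as the strict minimum of A_c and A_j.

    Returns ``(anet, limiting)`` where ``limiting`` is "Ac" or "Aj" per point
    (ties labelled "Ac").  No co-limitation smoothing is applied.
    """
    j = electron_transport(lp, jmax)
    ac = fvcb_ac(vcmax, ci, o, kin, rl)
    aj = fvcb_aj(j, ci, kin.gammastar, rl)
    ac_arr = np.atleast_1d(np.asarray(ac, dtype=float))
    aj_arr = np.atleast_1d(np.asarray(aj, dtype=float))
    anet = np.minimum(ac_arr, aj_arr)
    limiting = np.where(ac_arr <= aj_arr, "Ac", "Aj")
    if np.ndim(ci) == 0:
        return float(anet[0]), str(limiting[0])
    return anet, limiting


# ---------------------------------------------------------------------------
# quadratic thermal response of A_growth
# ---------------------------------------------------------------------------


def quadratic_agrowth(qp: QuadraticParams, tl):
    """A_growth predicted by the quadratic thermal response at ``tl`` (degC)."""
    _require_finite(tl=tl)
    tl = np.asarray(tl, dtype=float)
    out = qp.a * tl * tl + qp.b * tl + qp.c
    return float(out) if np.ndim(out) == 0 else out


def topt_from_quadratic(qp: QuadraticParams) -> tuple[float, float]:
    """Closed-form thermal optimum of the quadratic: T_optA = -b/(2a), A_opt.

    Raises NoOptimumError when a >= 0 (no interior maximum).
    """
    if qp.a >= 0:
        raise NoOptimumError("quadratic has no maximum: a >= 0")
    topt_a = -qp.b / (2.0 * qp.a)
    return topt_a, quadratic_agrowth(qp, topt_a)
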