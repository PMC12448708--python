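"""Short-term temperature responses of Vcmax, Jmax, and A_growth.

Per tree, apparent capacities estimated at the four measurement leaf
temperatures (10/20/30/40 degC by design) are fit with a peaked Arrhenius
function (deactivation energy held at 200,000 J mol-1 to avoid
over-parameterisation), yielding the rate at the optimum (k_opt), the
thermal optimum (T_opt), and the activation energy (E_a).  The growth-CO2
operating point A_growth is fit with a quadratic in leaf temperature,
yielding T_optA = -b/(2a) and A_opt in closed form.  Rates standardised to
20 degC (Vcmax20, Jmax20) and their ratio feed the treatment ANOVAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .fvcb import (
    HD_DEFAULT,
    PeakedArrheniusParams,
    QuadraticParams,
    T0_C,
    peaked_arrhenius,
    quadratic_agrowth,
    topt_from_quadratic,
)

__all__ = [
    "ThermalResponseFit",
    "UnfittableResponseError",
    "fit_peaked",
    "fit_quadratic_agrowth",
    "standardise_at_20",
    "ratio_j_v",
    "bootstrap_peaked_se",
]

_TOPT_BOUNDS_K = (273.15, 333.15)
_EA_BOUNDS = (1.0, 199_999.0)


class UnfittableResponseError(RuntimeError):
    """Fewer than three distinct temperatures, or a rank-deficient design."""


@dataclass(frozen=True)
class ThermalResponseFit:
    """One fitted thermal response (peaked Arrhenius or quadratic)."""

    process: str  # "Vcmax" | "Jmax" | "Agrowth"
    params: PeakedArrheniusParams | QuadraticParams
    kopt: float | None  # peaked only
    topt_c: float | None  # peaked: T_opt; quadratic: T_optA (degC)
    ea: float | None  # peaked only
    aopt: float | None  # quadratic only
    value_at_20: float | None
    ssr: float
    n: int
    flags: tuple[str, ...] = ()

    @property
    def accepted(self) -> bool:
        return not self.flags


def _check_points(tleaf_c, rate, min_temps=3):
    t = np.asarray(tleaf_c, dtype=float)
    y = np.asarray(rate, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if np.unique(t).size < min_temps:
        raise UnfittableResponseError(
            f"need >= {min_temps} distinct temperatures, got {np.unique(t).size}"
        )
    return t, y


def fit_peaked(
    tleaf_c,
    rate,
    process: str = "Vcmax",
    hd: float = HD_DEFAULT,
    extrapolation_margin_c: float = 15.0,
) -> ThermalResponseFit:
    """Fit the peaked Arrhenius response to (leaf temperature degC, rate) points.

    Free parameters are kopt, topt (bounded to [0, 60] degC), and ea
    (bounded to (0, hd)); hd stays fixed.  A deterministic multi-start over
    activation energies guards against local minima.  Monotone data push topt
    to the search boundary and are flagged "topt extrapolated" rather than
    raising; a flat response is flagged "degenerate flat response".
    """
    t_c, y = _check_points(tleaf_c, rate)
    t_k = t_c + T0_C
    if np.any(y <= 0):
        # peaked Arrhenius is strictly positive; non-positive rates cannot be fit
        raise UnfittableResponseError("rates must be > 0 for a peaked Arrhenius fit")

    kopt0 = float(y.max())
    topt0 = float(np.clip(t_k[np.argmax(y)], *_TOPT_BOUNDS_K))

    def residuals(x):
        kopt, topt, ea = x
        p = PeakedArrheniusParams(kopt=kopt, topt=topt, ea=ea, hd=hd)
        return peaked_arrhenius(p, t_k) - y

    best = None
    for ea0 in (30_000.0, 65_000.0, 120_000.0):
        sol = least_squares(
            residuals,
            [kopt0, topt0, ea0],
            bounds=([1e-6, _TOPT_BOUNDS_K[0], _EA_BOUNDS[0]],
                    [np.inf, _TOPT_BOUNDS_K[1], min(_EA_BOUNDS[1], hd - 1.0)]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
        )
        ssr = float(np.sum(sol.fun**2))
        key = (round(ssr, 12), round(float(sol.x[1]), 8))
        if best is None or key < best[0]:
            best = (key, sol, ssr)
    _, sol, ssr = best
    kopt, topt_k, ea = (float(v) for v in sol.x)

    flags = []
    if not sol.success:
        flags.append("optimizer did not converge")
    topt_c = topt_k - T0_C
    lo_b, hi_b = _TOPT_BOUNDS_K
    at_boundary = topt_k <= lo_b + 1e-6 or topt_k >= hi_b - 1e-6
    if at_boundary:
        flags.append("topt at boundary")
    if not (t_c.min() - extrapolation_margin_c <= topt_c <= t_c.max() + extrapolation_margin_c):
        flags.append("topt extrapolated")
    if ea <= 100.0 or (y.max() - y.min()) < 1e-9 * max(abs(y.max()), 1.0):
        flags.append("degenerate flat response")

    params = PeakedArrheniusParams(kopt=kopt, topt=topt_k, ea=ea, hd=hd)
    return ThermalResponseFit(
        process=process,
        params=params,
        kopt=kopt,
        topt_c=topt_c,
        ea=ea,
        aopt=None,
        value_at_20=float(peaked_arrhenius(params, 20.0 + T0_C)),
        ssr=ssr,
        n=int(y.size),
        flags=tuple(flags),
    )


def fit_quadratic_agrowth(tleaf_c, agrowth) -> ThermalResponseFit:
    """Ordinary least squares quadratic fit of A_growth against leaf temperature.

    T_optA and A_opt follow in closed form from the vertex; an upward-opening
    parabola (a >= 0) is flagged "no optimum" instead of raising.
    """
    t, y = _check_points(tleaf_c, agrowth)
    X = np.column_stack([t**2, t, np.ones_like(t)])
    if np.linalg.matrix_rank(X) < 3:
        raise UnfittableResponseError("rank-deficient quadratic design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = (float(v) for v in coef)
    qp = QuadraticParams(a=a, b=b, c=c)
    ssr = float(np.sum((X @ coef - y) ** 2))
    flags = []
    if a >= 0:
        flags.append("no optimum")
        topt_a = aopt = None
    else:
        topt_a, aopt = topt_from_quadratic(qp)
    return ThermalResponseFit(
        process="Agrowth",
        params=qp,
        kopt=None,
        topt_c=topt_a,
        ea=None,
        aopt=aopt,
        value_at_20=float(quadratic_agrowth(qp, 20.0)),
        ssr=ssr,
        n=int(y.size),
        flags=tuple(flags),
    )


def standardise_at_20(fit: ThermalResponseFit) -> float:
    """Rate at a common 20 degC leaf temperature (293.15 K for peaked fits)."""
    if fit.value_at_20 is None:
        raise ValueError("fit carries no 20 degC value")
    return fit.value_at_20


def ratio_j_v(fit_j: ThermalResponseFit, fit_v: ThermalResponseFit) -> tuple[float, tuple[str, ...]]:
    """Jmax20/Vcmax20 with flags propagated from either parent fit."""
    flags = tuple(f"Jmax fit: {f}" for f in fit_j.flags) + tuple(
        f"Vcmax fit: {f}" for f in fit_v.flags
    )
    return standardise_at_20(fit_j) / standardise_at_20(fit_v), flags


def bootstrap_peaked_se(
    tleaf_c,
    rate,
    n_boot: int = 500,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, float]:
    """Nonparametric bootstrap standard errors for kopt, topt, ea.

    Temperature points are resampled with replacement; resamples with fewer
    than three distinct temperatures are skipped (standard for n=4 designs).
    """
    t = np.asarray(tleaf_c, dtype=float)
    y = np.asarray(rate, dtype=float)
    rng = np.random.default_rng(seed)
    draws = {"kopt": [], "topt_c": [], "ea": []}
    for _ in range(n_boot):
        idx = rng.integers(0, t.size, size=t.size)
        if np.unique(t[idx]).size < 3:
            continue
        try:
            fit = fit_peaked(t[idx], y[idx], **fit_kwargs)
        except UnfittableResponseError:
            continue
        draws["kopt"].append(fit.kopt)
        draws["topt_c"].append(fit.topt_c)
        draws["ea"].append(fit.ea)
    return {
        f"se_{k}": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        for k, v in draws.items()
    }
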