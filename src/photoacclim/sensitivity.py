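"""Robustness analyses: alternative Rubisco kinetics and cuticular conductance.

Two checks probe whether apparent Vcmax/Jmax conclusions depend on analysis
conventions rather than biology: (i) refitting every curve under an
alternative Rubisco kinetic parameter set (rice or potato presets instead of
tobacco) and (ii) correcting Ci for water loss through the cuticle before
refitting, using the standard partitioning in which the cuticular pathway
carries water but no CO2:

    gsw_stomatal = gsw_measured - g_cw
    Ci'          = Ca - 1.6 A / gsw_stomatal

applied in delta form, Ci' = Ci - 1.6 A (1/(gsw - g_cw) - 1/gsw), so that
g_cw = 0 reproduces the input exactly whatever convention produced it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aci import fit_aci, qc_filter
from .fvcb import KineticsSet, LightParams, available_kinetics, load_kinetics

__all__ = ["refit_with_kinetics", "cuticular_correct"]

_CURVE_KEYS = ["tree_id", "t_leaf"]


def _fit_curves(curves: pd.DataFrame, kin: KineticsSet, lp, **kwargs) -> pd.DataFrame:
    rows = []
    for keys, curve in curves.groupby(_CURVE_KEYS, sort=True):
        try:
            fit = qc_filter(fit_aci(curve, kin, lp, **kwargs), curve)
            rows.append(
                dict(zip(_CURVE_KEYS, keys))
                | {
                    "vcmax": fit.vcmax,
                    "jmax": fit.jmax,
                    "rl": fit.rl,
                    "qc_accepted": fit.qc_accepted,
                }
            )
        except Exception:
            rows.append(
                dict(zip(_CURVE_KEYS, keys))
                | {"vcmax": np.nan, "jmax": np.nan, "rl": np.nan, "qc_accepted": False}
            )
    return pd.DataFrame(rows)


def refit_with_kinetics(
    curves: pd.DataFrame,
    kinetics_name: str,
    base_name: str = "tobacco",
    lp: LightParams | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every curve under two kinetic presets and join the results per curve.

    Returns one row per curve with ``vcmax``/``jmax`` under the base preset,
    ``vcmax_alt``/``jmax_alt`` under the alternative, and relative
    differences.  Identical presets give relative differences of exactly 0.
    """
    for name in (kinetics_name, base_name):
        if name not in available_kinetics():
            raise KeyError(
                f"unknown kinetics preset {name!r}; available: {available_kinetics()}"
            )
    if curves.empty:
        return pd.DataFrame(
            columns=_CURVE_KEYS
            + ["vcmax", "jmax", "vcmax_alt", "jmax_alt",
               "vcmax_rel_diff", "jmax_rel_diff"]
        )
    lp = lp or LightParams()
    base = _fit_curves(curves, load_kinetics(base_name), lp, **fit_kwargs)
    alt = _fit_curves(curves, load_kinetics(kinetics_name), lp, **fit_kwargs)
    merged = base.merge(alt, on=_CURVE_KEYS, suffixes=("", "_alt"))
    merged["vcmax_rel_diff"] = (merged["vcmax_alt"] - merged["vcmax"]) / merged["vcmax"]
    merged["jmax_rel_diff"] = (merged["jmax_alt"] - merged["jmax"]) / merged["jmax"]
    return merged


def cuticular_correct(curve: pd.DataFrame, g_cw_mmol: float) -> pd.DataFrame:
    """Recompute Ci after removing cuticular water loss from stomatal conductance.

    ``g_cw_mmol`` is the cuticular conductance to water in mmol H2O m-2 s-1
    (measured gs stays in mol m-2 s-1).  The correction lowers Ci wherever
    A > 0, is continuous and monotone in g_cw, and affects low-gs leaves the
    most.  g_cw = 0 returns the curve unchanged.
    """
    g_cw = g_cw_mmol / 1000.0
    if g_cw < 0:
        raise ValueError("g_cw must be >= 0")
    gs = np.asarray(curve["gs"], dtype=float)
    if np.any(g_cw >= gs):
        raise ValueError(
            "g_cw must be below the measured total conductance of every point"
        )
    out = curve.copy()
    if g_cw == 0:
        return out
    anet = np.asarray(curve["anet"], dtype=float)
    delta = 1.6 * anet * (1.0 / (gs - g_cw) - 1.0 / gs)
    out["ci"] = np.asarray(curve["ci"], dtype=float) - delta
    return out
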