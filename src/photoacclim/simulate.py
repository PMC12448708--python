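"""Synthetic CO2 x warming gas-exchange study with known ground truth.

The generator emulates a glasshouse design: two replicate years, five boreal
species, a factorial of three growth-temperature levels (0T/4T/8T) and two
growth-CO2 levels (AC 410 ppm, EC 750 ppm), n trees per species x treatment
cell, A/Ci curves at four leaf temperatures over the instrument's 12-step
Ca sequence (the 400 step appears twice: first measurement and
post-low-CO2 recovery).

Ground truth: each tree carries peaked-Arrhenius parameters for Vcmax and
Jmax.  Warming reduces photosynthetic capacity multiplicatively (defaults
x0.90 at 4T, x0.70 at 8T); growth CO2 leaves capacity unchanged.  Tree
random intercepts are mean-one lognormal (10% CV by default).  Intercellular
CO2 follows a fixed supply closure Ci = 0.72 Ca, stomatal conductance is
back-computed from Fick's law in water units, and additive Gaussian noise is
applied to A_net.  Everything is reproducible from (config, seed): elevated
CO2 raises A_growth and its thermal optimum purely through the physics of
measuring at the growth Ca, not through an injected effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fvcb import (
    KineticsSet,
    LightParams,
    O2_DEFAULT,
    PeakedArrheniusParams,
    T0_C,
    arrhenius_adjust,
    electron_transport,
    fvcb_ac,
    fvcb_aj,
    load_kinetics,
)

__all__ = [
    "StudyConfig",
    "DEFAULT_SPECIES",
    "assign_true_parameters",
    "generate_study",
    "inject_missingness",
    "CA_SEQUENCE",
]

# instrument Ca step sequence, umol mol-1: 400 first, low ramp, then 400 again
CA_SEQUENCE = (400, 300, 200, 150, 100, 50, 400, 600, 800, 1000, 1500, 2000)

DEFAULT_SPECIES = (
    "white_spruce",
    "black_spruce",
    "jack_pine",
    "tamarack",
    "paper_birch",
)

# species-level capacity baselines at the thermal optimum, umol CO2 m-2 s-1
_KOPT_V_BASELINE = {
    "white_spruce": 90.0,
    "black_spruce": 100.0,
    "jack_pine": 110.0,
    "tamarack": 120.0,
    "paper_birch": 130.0,
}


@dataclass(frozen=True)
class StudyConfig:
    """Design and generative parameters of one synthetic study."""

    seed: int
    species: tuple[str, ...] = DEFAULT_SPECIES
    years: tuple[int, ...] = (2019, 2021)
    t_growth_levels: tuple[str, ...] = ("0T", "4T", "8T")
    co2_levels: tuple[tuple[str, float], ...] = (("AC", 410.0), ("EC", 750.0))
    n_trees: int = 5
    leaf_temps_c: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    ca_sequence: tuple[float, ...] = CA_SEQUENCE
    noise_sd: float = 0.5  # additive SD on A_net, umol m-2 s-1
    tree_sd_frac: float = 0.10  # lognormal CV of tree random intercepts
    ci_ca_ratio: float = 0.72  # mean supply-closure target
    ci_ca_sd: float = 0.02  # between-tree SD of the Ci/Ca target
    # true thermal-response parameters (shared across species except kopt)
    kopt_v_baseline: tuple[float, ...] = tuple(
        _KOPT_V_BASELINE[s] for s in DEFAULT_SPECIES
    )
    jv_opt_ratio: float = 1.5  # kopt_J / kopt_V
    topt_v_c: float = 35.0
    topt_j_c: float = 30.0
    ea_v: float = 50_000.0
    ea_j: float = 40_000.0
    rl25: float = 1.2
    # treatment effects on true parameters
    kopt_warming_mult: tuple[tuple[str, float], ...] = (
        ("0T", 1.0),
        ("4T", 0.90),
        ("8T", 0.70),
    )
    kopt_co2_mult: tuple[tuple[str, float], ...] = (("AC", 1.0), ("EC", 1.0))
    topt_warming_shift_per_degc: float = 0.0  # optional degC of Topt per degC warming
    warming_degc: tuple[tuple[str, float], ...] = (
        ("0T", 0.0),
        ("4T", 4.0),
        ("8T", 8.0),
    )
    corrupt_fraction: float = 0.0  # fraction of curves given one negative-Ci point
    o2: float = O2_DEFAULT
    q: float = 1800.0
    kinetics: str = "tobacco"

    def __post_init__(self) -> None:
        if self.n_trees < 1 or not self.species or not self.years:
            raise ValueError("all design counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.kopt_v_baseline) != len(self.species):
            raise ValueError("kopt_v_baseline must match species length")
        if not 0 <= self.corrupt_fraction < 1:
            raise ValueError("corrupt_fraction must be in [0, 1)")

    @property
    def n_curves(self) -> int:
        return (
            len(self.years)
            * len(self.species)
            * len(self.t_growth_levels)
            * len(self.co2_levels)
            * self.n_trees
            * len(self.leaf_temps_c)
        )

    @property
    def n_rows(self) -> int:
        return self.n_curves * len(self.ca_sequence)

    def light_params(self) -> LightParams:
        return LightParams(q=self.q)

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def assign_true_parameters(config: StudyConfig) -> pd.DataFrame:
    """Draw per-tree true thermal-response parameters (the ground truth).

    One row per year x species x growth-temperature x growth-CO2 x tree,
    fully deterministic from (config, config.seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    warming_mult = dict(config.kopt_warming_mult)
    co2_mult = dict(config.kopt_co2_mult)
    warming_degc = dict(config.warming_degc)
    kopt_v_by_species = dict(zip(config.species, config.kopt_v_baseline))
    sigma = config.tree_sd_frac

    rows = []
    for year in config.years:
        for species in config.species:
            for tgrow in config.t_growth_levels:
                for cgrow, ca_grow in config.co2_levels:
                    for i_tree in range(1, config.n_trees + 1):
                        # mean-one lognormal tree intercept, shared by V and J
                        tree_factor = float(
                            np.exp(rng.normal(-0.5 * sigma**2, sigma))
                        ) if sigma > 0 else 1.0
                        mult = warming_mult[tgrow] * co2_mult[cgrow]
                        topt_shift = (
                            config.topt_warming_shift_per_degc
                            * warming_degc[tgrow]
                        )
                        kopt_v = kopt_v_by_species[species] * mult * tree_factor
                        rows.append(
                            {
                                "tree_id": f"{year}-{species}-{tgrow}-{cgrow}-t{i_tree}",
                                "year": year,
                                "species": species,
                                "t_growth": tgrow,
                                "co2_growth": cgrow,
                                "ca_growth": ca_grow,
                                "kopt_v": kopt_v,
                                "topt_v_k": config.topt_v_c + topt_shift + T0_C,
                                "ea_v": config.ea_v,
                                "kopt_j": kopt_v * config.jv_opt_ratio,
                                "topt_j_k": config.topt_j_c + topt_shift + T0_C,
                                "ea_j": config.ea_j,
                                "rl25": config.rl25 * tree_factor,
                                "ci_ca": float(
                                    np.clip(
                                        rng.normal(config.ci_ca_ratio, config.ci_ca_sd),
                                        0.4,
                                        0.95,
                                    )
                                ),
                            }
                        )
    return pd.DataFrame(rows)


def _peaked(kopt, topt_k, ea, tl_k):
    p = PeakedArrheniusParams(kopt=kopt, topt=topt_k, ea=ea)
    from .fvcb import peaked_arrhenius

    return peaked_arrhenius(p, tl_k)


def generate_study(
    config: StudyConfig,
    truth: pd.DataFrame | None = None,
    kin: KineticsSet | None = None,
) -> pd.DataFrame:
    """Forward-simulate the full gas-exchange table from the ground truth.

    Row count = years x species x 6 treatments x n_trees x leaf temps x
    Ca steps.  Before noise, every generated A/Ci curve is monotone
    non-decreasing in Ca (both FvCB limitations increase with Ci).
    """
    if truth is None:
        truth = assign_true_parameters(config)
    kin = kin or load_kinetics(config.kinetics)
    lp = config.light_params()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    ca = np.asarray(config.ca_sequence, dtype=float)
    step_index = np.arange(ca.size)
    frames = []
    for tree in truth.itertuples(index=False):
        for tleaf in config.leaf_temps_c:
            tl_k = tleaf + T0_C
            kin_t = kin.at_leaf_temperature(tleaf)
            vcmax = _peaked(tree.kopt_v, tree.topt_v_k, tree.ea_v, tl_k)
            jmax = _peaked(tree.kopt_j, tree.topt_j_k, tree.ea_j, tl_k)
            rl = arrhenius_adjust(tree.rl25, kin.ea_rl, tleaf)
            ci = tree.ci_ca * ca
            j = electron_transport(lp, jmax)
            ac = fvcb_ac(vcmax, ci, config.o2, kin_t, rl)
            aj = fvcb_aj(j, ci, kin_t.gammastar, rl)
            anet_true = np.minimum(ac, aj)
            anet = anet_true + (
                rng.normal(0.0, config.noise_sd, size=ca.size)
                if config.noise_sd > 0
                else 0.0
            )
            gs = 1.6 * np.maximum(anet_true, 0.05) / (ca - ci)
            # cosmetic floor: keeps gs above the plausible cuticular range so
            # conductance-partitioning analyses remain applicable at every step
            gs = np.clip(gs, 0.03, None)
            frames.append(
                pd.DataFrame(
                    {
                        "tree_id": tree.tree_id,
                        "species": tree.species,
                        "year": tree.year,
                        "t_growth": tree.t_growth,
                        "co2_growth": tree.co2_growth,
                        "t_leaf": float(tleaf),
                        "ca": ca,
                        "ci": ci,
                        "anet": anet,
                        "gs": gs,
                        "q": lp.q,
                        "step_index": step_index,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)

    if config.corrupt_fraction > 0:
        curve_keys = table[["tree_id", "t_leaf"]].drop_duplicates()
        n_corrupt = int(round(config.corrupt_fraction * len(curve_keys)))
        rng_c = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
        chosen = curve_keys.iloc[
            rng_c.choice(len(curve_keys), size=n_corrupt, replace=False)
        ]
        for _, key in chosen.iterrows():
            mask = (
                (table["tree_id"] == key["tree_id"])
                & (table["t_leaf"] == key["t_leaf"])
                & (table["step_index"] == 5)  # the Ca=50 step
            )
            table.loc[mask, "ci"] = -5.0
    return table


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Drop whole curves (tree x leaf temperature) at random, never single points.

    Emulates the unbalanced per-cell sample sizes of a real campaign.
    """
    if not 0 <= rate < 0.5:
        raise ValueError("rate must be in [0, 0.5)")
    if rate == 0:
        return table.copy()
    curve_keys = table[["tree_id", "t_leaf"]].drop_duplicates().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n_drop = int(round(rate * len(curve_keys)))
    drop = curve_keys.iloc[rng.choice(len(curve_keys), size=n_drop, replace=False)]
    merged = table.merge(drop.assign(_drop=True), on=["tree_id", "t_leaf"], how="left")
    return (
        merged[merged["_drop"].isna()]
        .drop(columns="_drop")
        .reset_index(drop=True)
    )
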