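# Methods

## Forward model

Net CO2 assimilation is the strict minimum of the Rubisco-limited and
RuBP-regeneration-limited rates of the Farquhar–von Caemmerer–Berry (FvCB)
model; triose-phosphate-utilisation limitation is excluded (it matters only
under combinations of very high CO2, high light and low temperature, and is
likewise absent from the large-scale models these parameters feed). No
co-limitation smoothing is applied: the minimum rule is the simplest
faithful reading of the two limitation equations and matches the default of
widely used A/Ci fitting tools. Oxygen is fixed at 210 000 µmol mol⁻¹ (21%)
unless overridden.

Electron transport J is the lower root of the non-rectangular hyperbola
θJ² − J(αQ + Jmax) + αQJmax = 0 with curvature θ = 0.85 and quantum yield
α = 0.24 mol electrons mol⁻¹ photons (conifer-typical values), and
Q = 1800 µmol photons m⁻² s⁻¹ (saturating light) during measurement.

Because mesophyll conductance is not modelled, Ci stands in for
chloroplastic CO2 and all capacities are *apparent* values. Kinetic
constants (Kc, Ko, Γ*, and R_L when fixed) follow a simple Arrhenius
response around 25 °C, k(T) = k25·exp[Ea(T−298.15)/(298.15·R·T)]. The
default preset ("tobacco") carries Bernacchi-style Ci-based tobacco
constants (Kc25 = 404.9, Ko25 = 278 400, Γ*25 = 42.75 µmol mol⁻¹ with their
standard activation energies); they live in one versioned data table
(`src/photoacclim/data/kinetics_presets.csv`) with a provenance column. The
"rice" and "potato" presets used by the kinetics-sensitivity analysis are
synthetic stand-ins at approximate literature magnitudes (their source
tables are not redistributed here); the sensitivity module consequently
claims only rank/sign preservation of treatment contrasts, which does not
depend on the exact alternative constants.

## Curve fitting

Each curve (one tree × one leaf temperature, the instrument's 12-step Ca
sequence 400, 300, 200, 150, 100, 50, 400, 600, 800, 1000, 1500, 2000
µmol mol⁻¹) is fit by bounded nonlinear least squares (`scipy`'s trust
region reflective method with a piecewise-analytic Jacobian) over
(Vcmax, Jmax, R_L), with kinetics evaluated at the curve's mean leaf
temperature. R_L is estimated jointly by default, bounded to
[0, 10] µmol m⁻² s⁻¹; a fixed-R_L mode (preset value, Arrhenius-adjusted)
is available because both conventions are defensible.

Initialisation is analytic — Vcmax from inverting the Rubisco-limited
equation on the low-Ci points, Jmax from the electron transport required at
the highest-Ci point — followed by a deterministic five-point multiplicative
multi-start; ties break by lowest SSR then lowest Vcmax. The bulk pipeline
uses a deterministic escalation rule: when the analytic-guess start
converges with R² ≥ 0.98 the remaining starts are skipped, otherwise the
full multi-start runs. Search bounds ([0.5, 2000]) are deliberately wider
than the QC acceptance range so that out-of-range estimates are reported
and rejected rather than silently clipped.

A profile-flatness check flags Jmax as unidentifiable when increasing it by
25–50% leaves the SSR unchanged relative to the curve's total variance
(threshold 10⁻³): this happens when RuBP regeneration never binds, e.g.
curves confined to sub-saturating Ci.

### Quality control

Reproducible rules replace visual curve screening:

- any negative Ci point in the raw curve → reject ("negative Ci");
- Vcmax or Jmax outside [10, 500] µmol m⁻² s⁻¹ → reject;
- optimizer non-convergence → reject (never silent);
- R² < 0.90 → reject ("poor fit");
- systematic residuals: a one-sided Wald–Wolfowitz runs test on residual
  signs (ordered by Ci, z ≤ −2.58) *combined with* R² < 0.97. The joint
  rule is needed because sign structure alone arises in ~0.2% of 12-point
  curves under pure noise; requiring a visibly imperfect fit as well makes
  the false-rejection rate negligible while still catching model misfit.

QC is idempotent and order-independent across curves.

The growth-CO2 operating point (A_growth, gs, Ci/Ca) is read from the step
nearest Ca = 400 (AC) or Ca = 800 (EC, the closest step to 750 ppm); when
the 400 step occurs twice, the later (post-low-CO2-recovery) occurrence is
used.

## Thermal responses

Vcmax and Jmax across the four leaf temperatures are fit per tree with the
peaked Arrhenius function

f(T) = k_opt · H_d · exp[E_a(T−T_opt)/(T·R·T_opt)] / (H_d − E_a(1 − exp[H_d(T−T_opt)/(T·R·T_opt)]))

with H_d fixed at 200 000 J mol⁻¹ to avoid over-parameterisation. The
optimisation parameterises T_opt directly (bounds 273.15–333.15 K,
E_a ∈ (0, H_d)), with a three-point deterministic multi-start over
activation energies; with four temperatures and fixed H_d the three free
parameters are identifiable. Monotone data push T_opt to the boundary and
are flagged ("topt extrapolated", i.e. outside the measured range ± 15 °C)
rather than raising; flat responses are flagged degenerate. Vcmax20/Jmax20
are the fitted function at 293.15 K, and always ≤ k_opt by construction.

A_growth is fit with an ordinary-least-squares quadratic in leaf
temperature (°C); T_optA = −b/(2a) and A_opt follow in closed form, and an
upward-opening parabola is flagged "no optimum".

Fits are per tree (so treatment summaries are means of individual-tree
parameters, matching how repeated-measures designs are reported); a pooled
mode is not the default. Standard errors for derived thermal parameters are
available via a seeded nonparametric bootstrap over temperature points
(500 resamples by default); the bulk pipeline reports point estimates and
flags, with the bootstrap run on demand.

## Statistical inference

Responses measured repeatedly per tree (A_growth, per-curve Vcmax/Jmax) use
linear mixed models with tree random intercepts (statsmodels `MixedLM`),
with leaf temperature as a continuous covariate. Derived parameters (one
value per tree) use ordinary linear models; a singular random-intercept
variance triggers a fixed-effects refit with a warning.

Fixed-effect selection minimises AICc (= −2ℓ + 2k + 2k(k+1)/(n−k−1), with k
counting mean and variance parameters) over *all* marginality-respecting
sub-models of the requested factorial, fit by maximum likelihood; ties go
to the smaller model, and the candidate ordering is canonical so the choice
is reproducible. The chosen model is refit by REML for reporting. Terms
dropped by selection appear as blank cells in the output tables.

Per-term F statistics are Wald tests on the term's design columns. The
denominator df uses a between-within (containment-style) split: terms whose
columns are constant within trees are referred to (n_trees − rank of the
between-tree design); within-tree terms use (n_obs − n_trees − n_within
parameters). On balanced designs this reproduces classical repeated-measures
ANOVA; simulation (seeded, in the test suite) confirms a type-I rate of
~0.045 at α = 0.05. With treatment (dummy) coding the Wald tests are exact
for balanced data; strongly unbalanced designs would make them
order-dependent, a known limitation.

Tukey post-hoc comparisons across the six treatment cells use the
studentized-range correction on the per-tree values; the compact letter
display is built by insert-and-absorb, so cells sharing no letter differ at
α = 0.05 by construction.

## Synthetic study generator

The generator emulates the reference design: 2 replicate years × 5 boreal
species × (3 growth temperatures × 2 growth CO2) × 5 trees × 4 leaf
temperatures × the 12-step Ca sequence (14 400 rows). Defaults:

| parameter | default | rationale |
|---|---|---|
| k_optV baseline | 90–130 µmol m⁻² s⁻¹ by species | boreal-conifer/birch magnitudes; keeps 10 °C rates above the QC floor |
| k_optJ / k_optV | 1.5 | Jmax20/Vcmax20 ≈ 2, typical for cold-climate trees |
| T_optV, T_optJ | 35 °C, 30 °C | canonical capacity optima |
| E_aV, E_aJ | 50 000, 40 000 J mol⁻¹ | mid-range activation energies |
| R_L,25 | 1.2 µmol m⁻² s⁻¹ | ~1–1.5% of Vcmax25 |
| warming multipliers on k_opt | ×0.90 (4T), ×0.70 (8T) | the injected acclimation effect |
| CO2 multiplier on k_opt | ×1.0 | capacity unaffected by growth CO2 |
| tree random intercept | mean-one lognormal, 10% CV | between-tree variation |
| A_net noise | additive Gaussian, SD 0.5 µmol m⁻² s⁻¹ | instrument-scale scatter |
| Ci/Ca target | 0.72 (SD 0.02 between trees) | near-constant supply–demand balance |

Ci follows the fixed-ratio supply closure Ci = (Ci/Ca)·Ca rather than a
stomatal-optimisation model: the ratio is near-constant in the reference
system and gs realism is not needed for any fitted quantity. gs is
back-computed from Fick's law in water units (1.6·A/(Ca−Ci)) and floored at
0.03 mol m⁻² s⁻¹ so conductance-partitioning analyses remain applicable at
every step; the gs column is declared cosmetic. An optional warming shift
of the process thermal optima (°C per °C of growth warming) is available
but defaults to 0, reflecting that capacity optima are typically the least
responsive parameters; the elevated-CO2 increase of T_optA and of A_growth
are *emergent* — they arise because EC plants are read at Ca ≈ 800 where
photorespiration is suppressed — and are not injected anywhere.

What the generator does **not** emulate: VPD/transpiration dynamics,
mesophyll or cuticular conductance in the truth (the cuticular module is a
correction applied at analysis time), seasonal drift, instrument drift, or
non-Gaussian outliers. Passing tests therefore demonstrate correctness of
the estimation machinery under the stated generative assumptions, not
robustness to every artefact of field data.

Corruption (`corrupt_fraction`) gives a chosen fraction of curves one
negative-Ci point (at the Ca = 50 step), and `inject_missingness` drops
whole curves, never single points — emulating unbalanced per-cell sample
sizes. All randomness descends from one seed; identical configurations
produce byte-identical CSVs.

## Sensitivity analyses

*Kinetics swap*: every curve is refit under an alternative preset and the
paired table reports relative differences; the claim checked is that
treatment contrasts preserve sign and rank (Spearman ρ > 0.95 across
curves), not numerical equality.

*Cuticular conductance*: the cuticular pathway carries water but no CO2, so
the stomatal water conductance is gsw − g_cw and
Ci′ = Ca − 1.6A/(gsw − g_cw), applied in delta form
Ci′ = Ci − 1.6A(1/(gsw−g_cw) − 1/gsw) so g_cw = 0 reproduces the input
exactly regardless of the convention that produced the original Ci. The
correction is continuous and monotone in g_cw and largest for low-gs
leaves; g_cw at or above the measured conductance is an error.

## Problem sizes and numerical choices

The end-to-end acceptance check runs the full default study (1200 curves)
across 20 seeds; calibration simulations use 1000 null replicates (mixed
model) and 200 power replicates, and the acceptance script uses 400/200 —
sizes chosen to give stable Monte-Carlo estimates at interactive runtimes.
Optimiser tolerances are 10⁻¹⁰ (curve fits) and 10⁻¹² (thermal fits);
noiseless round-trips recover parameters to machine precision, and the grid
oracle (0.25-resolution exhaustive search) agrees with the NLS solution to
within one grid cell.

## Known limitations

- Apparent (Ci-based) capacities only; no mesophyll conductance model.
- No TPU limitation and no C4 pathway.
- Wald F-tests with treatment coding are exact for balanced designs only;
  Kenward–Roger or Satterthwaite df are out of scope.
- The alternative kinetic presets are labelled stand-ins; conclusions that
  depend on their exact values should not be drawn.
- Visual curve screening is approximated by the R²/runs rule; a human
  analyst might reject a handful of additional curves.
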