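# photoacclim

Analysis pipeline for **photosynthetic acclimation to elevated CO2 and
warming**, built for glasshouse-style experiments in which trees grown under
factorial growth-CO2 (AC ≈ 410 ppm / EC ≈ 750 ppm) and growth-temperature
(+0 / +4 / +8 °C) treatments are measured with multi-temperature A/Ci curves.
It is aimed at plant ecophysiologists who need a reproducible route from raw
gas-exchange tables to treatment-level inference, and it ships a synthetic
study generator with known ground truth so every stage can be validated
without access to a real campaign's data.

## What it computes

**1. Apparent photosynthetic capacity.** Each CO2-response curve is fit with
the Farquhar–von Caemmerer–Berry model of C3 photosynthesis, using
intercellular CO2 (Ci) in place of chloroplastic CO2:

```
A_c = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko)) − R_L          (Rubisco-limited)
A_j = J/4  (Ci − Γ*) / (Ci + 2Γ*) − R_L                     (RuBP-regeneration-limited)
θ J² − J (αQ + Jmax) + αQ Jmax = 0                           (J = lower root)
A_net = min(A_c, A_j)
```

with θ = 0.85, α = 0.24 and saturating light Q = 1800 µmol photons m⁻² s⁻¹.
Nonlinear least squares yields apparent Vcmax, Jmax and R_L per curve, with
reproducible quality control (negative Ci, parameters outside
[10, 500] µmol m⁻² s⁻¹, poor or systematically biased fits).

**2. Short-term thermal responses.** Per tree, capacities across the four
measurement leaf temperatures (10/20/30/40 °C) are fit with a peaked
Arrhenius function (deactivation energy H_d fixed at 200 000 J mol⁻¹),
yielding k_opt, T_opt and E_a, plus rates standardised to 20 °C (Vcmax20,
Jmax20). Net photosynthesis at the growth CO2 concentration (A_growth)
is fit with a quadratic in leaf temperature, with its optimum T_optA = −b/(2a)
and A_opt in closed form.

**3. Treatment inference.** Derived parameters are tested with linear (mixed)
models — tree-level random intercepts for repeated measures, AICc selection
of fixed effects over all marginality-respecting sub-models, per-term F
tests with a between-within denominator-df split, and Tukey post-hoc
comparisons across the six treatment cells with a compact letter display.

**4. Robustness.** Curve fits can be repeated under alternative Rubisco
kinetic presets (rice/potato vs the default tobacco constants) and under a
cuticular-conductance correction of Ci.

## Worked example

```python
from photoacclim import StudyConfig, generate_study, fit_study, derive_thermal

cfg = StudyConfig(seed=1)           # 2 years x 5 species x 6 treatments x 5 trees
study = generate_study(cfg)         # 14400 rows = 1200 A/Ci curves
fits = fit_study(study)             # apparent Vcmax/Jmax/R_L per curve + QC
derived = derive_thermal(fits)      # per-tree k_opt, T_opt, E_a, T_optA, A_opt

print(derived.groupby("t_growth")["vcmax_opt"].mean().round(1))
print(derived.groupby("co2_growth")[["topt_a", "a_opt"]].mean().round(2))
```

prints

```
t_growth
0T    111.4
4T     97.9
8T     76.6
Name: vcmax_opt, dtype: float64

            topt_a  a_opt
co2_growth
AC           20.80  15.22
EC           24.23  23.06
```

i.e. the +8 °C treatment reduces the fitted Vcmax optimum by ~31% (the
generator injects a 30% reduction), while elevated CO2 leaves capacity
untouched but raises A_opt by ~52% and shifts the A_growth thermal optimum
upward by ~3.4 °C — an emergent consequence of suppressed photorespiration
when measuring at the higher growth CO2, not an injected effect.

The same pipeline runs from the shell:

```bash
photoacclim run-all --seed 1 --outdir results/run1
photoacclim simulate --seed 1 --out study.csv
photoacclim fit-aci --input study.csv --out fits.csv
photoacclim sensitivity --input study.csv --kinetics rice --out paired.csv
```

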