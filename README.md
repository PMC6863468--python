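# rdacclim

Thermal acclimation of plant dark respiration, analysed across tissues.

When a plant experiences a new growth temperature for days to weeks, the
instantaneous response of dark respiration (R_d) to tissue temperature can
shift — classically a flattening of the response and/or a downward shift of
rates at a common temperature. `rdacclim` implements the full analysis chain
used to quantify that acclimation separately for leaves, photosynthetic
stems, non-photosynthetic stems and roots:

1. **Curve fitting.** Each individual × tissue temperature series is fit
   with the exponential-quadratic (log-polynomial) model

   ```
   R(T) = exp(a + b·T + c·T²)
   ```

   where `T` is tissue temperature (°C), `a` is the log rate at 0 °C
   (µmol g⁻¹ s⁻¹ on a dry-mass basis), `b` (°C⁻¹) the relative sensitivity
   near 0 °C, and `c` (°C⁻²) its change with warming. Fitting is exact
   least squares on the log scale (default) or iterative least squares on
   the flux scale; RMSE is always reported in flux units.

2. **Hierarchical inference.** The fitted parameters are regressed on
   species, acclimation temperature T_a (continuous), tissue class and the
   T_a × tissue interaction, with a random intercept per individual plant
   (REML). The package provides type-II Wald χ² tests per term,
   least-squares-mean slopes/intercepts of each parameter versus T_a per
   tissue class with Satterthwaite degrees of freedom, planned
   photosynthetic-versus-non-photosynthetic slope contrasts, and
   Tukey-adjusted species marginal means.

3. **Acclimated surfaces and homeostasis.** From the per-tissue parameter
   trends it reconstructs the acclimated surface `R_d(T_t; T_a)` and the
   homeostasis ratio

   ```
   Acclim_Homeo(T_a) = R_d(T_a; T_a) / R_d(25; 25)    (T_a < 25 °C)
                     = R_d(25; 25) / R_d(T_a; T_a)    (T_a > 25 °C)
   ```

   so 1 means perfectly homeostatic respiration at the acclimation
   temperature. It also computes per-individual ln(R_d,acc/V_cmax,acc)
   ratios (respiration relative to photosynthetic capacity, both evaluated
   at T_t = T_a) and feeds them through the same mixed model.

4. **Synthetic studies.** A generator reproduces the statistical structure
   the analysis assumes — the unbalanced 84-individual, 8-species × 5-T_a
   sampling design, linear parameter drift with T_a, species and individual
   effects on the basal rate, multiplicative lognormal measurement noise,
   and the jittered top measurement temperature — with the ground truth
   stored for recovery tests.

## Worked example

```python
from rdacclim import (make_design, draw_true_parameters, simulate_measurements,
                      fit_all_individuals, assemble_parameter_table,
                      fit_mixed_ancova)

design = make_design("table1", seed=1)          # 84 individuals, unbalanced
truth = draw_true_parameters(seed=1)            # non-Ps tissues acclimate
study = simulate_measurements(design, truth)

fits, failures = fit_all_individuals(study.records)
params = assemble_parameter_table(fits)
model = fit_mixed_ancova(params, "b")           # thermal-sensitivity parameter
print(model.lsm_trends()[["tissue_class4", "slope", "se", "df", "p"]].round(4))
```

```
  tissue_class4   slope      se        df       p
0          leaf -0.0003  0.0007  220.1526  0.6158
1       ps_stem -0.0020  0.0012  222.8874  0.0952
2    nonps_stem -0.0056  0.0010  222.7001  0.0000
3          root -0.0059  0.0007  220.1526  0.0000
```

The generating truth moves `b` by −0.005 °C⁻¹ per °C of acclimation in
roots and non-photosynthetic stems and not at all in photosynthetic
tissues; the marginal slopes recover exactly that pattern, with
Satterthwaite df close to the ~220 the design implies. Running the whole
pipeline instead:

```bash
rdacclim run-all --seed 1 --out results/
```

prints the homeostasis grid (rows: acclimation temperature; columns: tissue
class; 1 = fully homeostatic):

```
          leaf  ps_stem  nonps_stem  root  Average
T_a
15 C      0.42     0.40        0.76  0.73     0.58
20 C      0.66     0.65        0.93  0.91     0.79
30 C      0.67     0.68        0.99  0.95     0.82
35 C      0.46     0.48        0.98  0.86     0.70
Average   0.55     0.55        0.92  0.86     0.72
```

Non-photosynthetic tissues stay near 1 (strong acclimation of respiratory
rates at the growth temperature) while photosynthetic tissues do not — the
tissue-level contrast the package is built to detect. The stage-wise
subcommands `simulate`, `fit-curves`, `fit-models`, `acclim` and `report`
re-run any stage from the intermediate CSVs.

## Layout

- `rdacclim.synthetic` — study designs, ground truth, simulation
- `rdacclim.curves` — exponential-quadratic curve fitting (`ExpQuadraticCurve`)
- `rdacclim.ancova` — mixed-model ANCOVA (`AcclimationAncova`), Wald tests,
  marginal trends, contrasts
- `rdacclim.surface` — acclimated surfaces, `Acclim_Homeo`, R_d/V_cmax ratios
- `rdacclim.io`, `rdacclim.pipeline`, `rdacclim.cli` — CSV schema, orchestration,
  command line

See `docs/methods.md` for the statistical methods, defaults and limitations.
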