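# qctfe — vertebral strength from low-dose CT, simulated end to end

`qctfe` asks a practical question from osteoporosis imaging: **how far can
the CT radiation dose be reduced before finite-element (FE) predicted
vertebral failure load stops agreeing with the full-dose prediction?**
Two dose-reduction strategies compete:

* **tube-current reduction** — fewer photons in every projection
  (quantum + electronic noise grows in each ray);
* **sparse sampling** — full tube current, but only every k-th projection
  angle is acquired.

Because patient scans cannot be re-acquired at seven dose levels, the
package builds the entire experiment synthetically: vertebra-like digital
phantoms with a QCT calibration insert, a parallel-beam CT simulator with
both dose-reduction mechanisms, statistical iterative reconstruction
(ordered-subset separable paraboloidal surrogates with momentum),
threshold/morphology segmentation, HU→BMD calibration, density-modulus
material mapping onto linear tetrahedral meshes, and a displacement-
controlled nonlinear compression analysis whose force-displacement peak
is the failure load FL.  Agreement of each reduced-dose condition
(D50P100, D25P100, D10P100 for tube current; D100P50, D100P25, D100P10
for sparse sampling) with the reference D100P100 is quantified by R² of
the per-subject FL regression, the root-mean-square two-point coefficient
of variation

    RMSCV = 100 · sqrt( mean_i [ (|FL_ref,i − FL_red,i| / √2) / FL̄_i ]² )  [%],

and Bland-Altman bias `mean(FL_ref − FL_red)` with ±1.96 SD limits of
agreement.  The core mechanical model maps each element's HU to apparent
density ρ_app = 47 + 1.122·HU (mg/cc), axial modulus
E_z = −349 + 5.82·ρ_app (MPa) with transversely isotropic ratios
(E_x = E_y = 0.333 E_z, G_xy = 0.121 E_z, G_xz = G_yz = 0.157 E_z), and
ash-density power laws for the principal-stress limits
(σ = 137 ρ_ash^1.88 below 0.317 g/cc, 114 ρ_ash^1.72 above;
σ_min = 65.1 ρ_ash^1.93) plus a plastic-strain capacity
ε_AB = −0.00315 + 0.0728 ρ_ash.

See `docs/methods.md` for models, assumptions and defaults.

## Worked example

Run the full seven-condition experiment on a 12-subject synthetic cohort
(about three minutes on one CPU):

```python
from qctfe import pipeline

config = pipeline.RunConfig(master_seed=1)
results, summary, bmd = pipeline.run_experiment(config, outdir="run1")
print(summary[["condition", "fl_mean_n", "r2", "rmscv_pct", "bias_n"]].round(2))
print(bmd.round(1))
```

which prints (master seed 1):

```
condition  fl_mean_n   r2  rmscv_pct  bias_n
 D100P100    2025.90 1.00       0.00    0.00
  D50P100    1977.09 0.99       3.37   48.82
  D25P100    1918.80 0.98       6.94  107.11
  D10P100    1508.46 0.93      28.85  517.44
  D100P50    1981.72 0.99       5.07   44.18
  D100P25    2008.62 0.99       3.03   17.28
  D100P10    1974.17 0.99       4.79   51.74

condition  bmd_mean_mgcc  bmd_sd_mgcc  n_healthy  n_osteopenia  n_osteoporotic
 D100P100           92.9         17.5          1             8               3
  D50P100           89.7         17.2          1             8               3
  D25P100           94.6         15.5          1            10               1
  D10P100          155.4         30.3         11             1               0
  D100P50           91.6         17.5          1             7               4
  D100P25           91.8         18.8          1             7               4
  D100P10           90.8         18.8          1             7               4
```

Reading the table: along the tube-current series the agreement with the
full-dose reference degrades monotonically (R² 0.99 → 0.98 → 0.93, RMSCV
3.4 → 6.9 → 28.9 %), while the sparse-sampling series stays close to the
reference even at a 90 % dose cut (R² 0.99, RMSCV 4.8 %) — sparse
sampling is the better route to low-dose FE strength prediction.  The
BMD table shows the companion artifact: at 10 % tube current the measured
trabecular BMD inflates from ~93 to ~155 mg/cc and 11 of 12 subjects are
misclassified as healthy, whereas sparse sampling leaves BMD essentially
unchanged.  `run1/` additionally contains the per-subject results CSV,
both summary tables, scatter/Bland-Altman figures and the exact
configuration with its hash.

A command-line interface mirrors the stages (`qctfe phantom | simulate |
reconstruct | fe | stats | run-all`); `qctfe run-all --seed 1 --outdir
run1` reproduces the example above.

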