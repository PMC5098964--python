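# elefoot

Pedobarographic analysis of walking elephants: isolate individual footsteps
from pressure-platform recordings, register footprints of the same foot to a
template, extract regional peak pressures at anatomical landmarks, compute
centre-of-pressure (COP) trajectories, and compare trajectories between feet
and cohorts.

## The problem

Foot disease is a leading welfare problem in captive elephants, and pressure
platforms offer a non-invasive window on foot loading. A walking elephant
crosses a 44 × 160 sensor plate (0.605 m × 2.122 m, sampled at 100 Hz); the
recording `p(x, y, t)` contains several overlapping footfalls that must be

1. **segmented** — footsteps are connected components of the voxel set
   `{(t, row, col) : p ≥ 5 kPa}` under a gap-bridging spatio-temporal
   adjacency, then assessed for spatio-temporal completeness and assigned a
   foot identity (FL/FR/HL/HR);
2. **registered** — every peak-pressure image (per-pixel max over stance) of
   a foot is aligned to that foot's template (the first complete step) by a
   rigid transform, so pixels correspond anatomically across steps;
3. **measured** — seven regions of interest (ROIs) are digitized on the mean
   image: the nail midpoints of digits i–v (medial→lateral), the mid-sole and
   the caudal heel. At each ROI (and at four ±1-pixel sensitivity positions
   around it) the peak pressure is read through a 3 × 3, σ = 1 px Gaussian
   kernel;
4. **compared** — per-step COP paths (the pressure-weighted centroid per
   frame) are time-normalized to 101 stance-percent samples, averaged per
   foot, and compared pairwise with axis-wise Pearson correlations
   (mediolateral `x_r`, cranio-caudal `y_r`), RMSE on centred untransformed
   data, and RMSD after ordinary Procrustes analysis (OPA) with scaling and
   reflection:

   minimize ‖A − β B Γ‖² over translation, orthogonal Γ (det ±1 when
   reflection is allowed) and scale β, solved in closed form via the SVD of
   the cross-covariance matrix; RMSD = √(mean per-point squared residual).

A synthetic-data module generates records with known ground truth — step
masks, foot identities, analytically integrated COP paths, regional peak
pressures — emulating the plate, a slow walk (1.2 m/s, Fr ≈ 0.07) and the
loading pattern reported for elephants (peaks on the lateral digits, low
pressures under the heel, caudal-to-cranial COP with a lateral deviation at
impact), so every downstream stage has a recovery test.

## Worked example

```python
from elefoot.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(out_dir="out", seed=1))
print(bundle["comparisons"].round(3).to_string(index=False))
```

```
 pair    x_r   y_r  rmse  rmsd  scale  reflect
FL-FR -0.357 0.998 0.011 0.007   True     True
FL-HL  0.804 0.996 0.006 0.005   True     True
FL-HR -0.565 0.999 0.013 0.005   True     True
FR-HL -0.808 0.999 0.011 0.003   True     True
FR-HR  0.944 1.000 0.003 0.002   True     True
HL-HR -0.917 0.999 0.012 0.002   True     True
```

All pairs share the strongly conserved cranio-caudal progression
(`y_r ≈ 1`); mediolateral correlations are positive for same-side pairs and
negative across sides, because left and right feet mirror their lateral
impact deviation — after Procrustes superimposition with reflection the
residual RMSD is small for every pair. The per-subject summary from the same
run shows forefeet loaded above hindfeet, at adult-elephant magnitudes:

```
foot  mean_max_pressure_kpa  se_max_pressure_kpa  n_steps
  FL                  246.3                 10.0        3
  FR                  249.4                  1.0        3
  HL                  232.6                  4.0        3
  HR                  233.3                  8.9        3
```

Descriptive cohort statistics for the published five-subject African
elephant table are available from `elefoot.stats`:

```python
from elefoot.stats import african_cohort, weighted_mean
t = african_cohort()
weighted_mean(t["body_mass_kg"], t["n_steps"])   # 2059.52 -> 2060 kg
t["velocity_ms"].mean()                          # 1.234   -> 1.2 m/s
```

## Command line

```bash
elefoot simulate --out-dir data --trials 3 --seed 0   # records + truth.json
elefoot segment --record data/SYN1_trial000 --out steps.csv
elefoot run-all --out-dir out --seed 0                # full pipeline
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's end-to-end computation from
scratch: it simulates a seeded synthetic cohort, pushes it through
segmentation, registration, ROI extraction and COP comparison, recomputes
the cohort descriptive statistics from the bundled subject table, and writes
the JSON report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | role |
| --- | --- |
| `elefoot.pressure_io` | plate/record/metadata types; sparse CSV+JSON record format; tolerant table reader |
| `elefoot.synthetic` | ground-truthed pressure-record generator |
| `elefoot.segment` | spatio-temporal footstep isolation, completeness, foot identity |
| `elefoot.register` | peak images, template selection, rigid registration |
| `elefoot.roi` | ROI digitization, Gaussian-kernel extraction, sensitivity table |
| `elefoot.cop` | COP trajectories, time normalization, Pearson/RMSE/Procrustes comparison |
| `elefoot.stats` | Froude numbers, weighted means, mean ± s.e. summaries, cohort ratios |
| `elefoot.pipeline`, `elefoot.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the model, parameter choices and limitations.
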