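# cornerflow

Measurement-and-prediction toolkit for surfactant-induced capillary corner
flow: pendant-drop tensiometry, contact-angle goniometry, corner-wetting
prediction, and time-lapse tip tracking, with seed-deterministic synthetic
generators for every stage.

## What it does

- **`cornerflow.younglaplace`** — integrates axisymmetric Young–Laplace drop
  shapes (fixed-step RK4 in arc length, analytic apex limit) and inverts them
  against observed pendant silhouettes to recover surface tension
  γ = Δρ·g·b²/β via a bounded Nelder–Mead search over apex radius and Bond
  number.
- **`cornerflow.imaging`** — segments a drop silhouette, extracts a sub-pixel
  edge (threshold-crossing interpolation per row, parabolic apex refinement),
  detects the substrate baseline, and measures the advancing contact angle as
  the interior angle between a straight tangent fit near the contact line and
  the baseline.
- **`cornerflow.corner`** — corner-wetting criterion (flow when
  α/2 + θc < 90°), critical corner angle α_th = 2·(90° − θ_min), maximum rise
  height in a rounded corner h = 2γ·cosθc/(ρ·g·d), and concentration-series
  bracketing of the flow onset.
- **`cornerflow.tracking`** — per-frame tip detection in a time-lapse stack
  and ramp/plateau kinetics (onset time, plateau-attainment time, mean
  climbing speed).
- **`cornerflow.synthetic`** — ground-truth generators: rendered pendant and
  sessile drop images, corner time-lapse stacks with ramp-plateau
  trajectories, and logistic concentration series. Identical seed and
  parameters give bit-identical output.
- **`cornerflow.pipeline` / `cornerflow.cli`** — YAML-configured multi-stage
  runs with JSON/CSV outputs.

## CLI

```sh
# predict corner flow and the capped rise height
cornerflow corner-predict --alpha 30 --theta 60 --gap 225e-6 --gamma 0.030

# generate synthetic inputs (with ground-truth JSON alongside)
cornerflow simulate --kind pendant   --out demo --seed 1
cornerflow simulate --kind sessile   --theta 60 --out demo
cornerflow simulate --kind timelapse --h-max 9e-3 --t-start 8 --t-end 15 --out demo

# analyse them
cornerflow tensiometry --image demo/pendant.png --calib 5e-6
cornerflow contact-angle --image demo/sessile.png --calib 5e-6
cornerflow track --stack demo/timelapse.tif --roi 28:36 \
    --baseline-row 280 --calib 50e-6 --interval-min 10

# or run a whole pipeline from YAML
cornerflow run --config pipeline.yaml
```

A pipeline config lists stages executed in order, e.g.

```yaml
outdir: out
seed: 1
stages:
  - {kind: simulate_timelapse, name: tl, h_max: 9e-3, t_start_h: 8, t_end_h: 15}
  - {kind: corner_predict, alpha_deg: 30, theta_deg: 60, gamma: 0.030, min_gap: 225e-6}
```

Output column names: profile CSVs are `x_m,z_m`; concentration series are
`concentration_M,gamma_N_per_m,theta_deg`; trajectories are `t_h,Hc_mm`.
Reports are schema-versioned JSON.

## Units and conventions

Strict SI internally (meters, N/m, kg/m³); degrees only at API boundaries.
Image row 0 is the top of the frame; physical z increases away from the drop
apex. Gravity defaults to 9.81 m/s².
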