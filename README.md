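# tolpal

Reaction–diffusion modelling and SpatialFRAP analysis of how the
outer-membrane lipoprotein **Pal** is redistributed to the division septum of
Gram-negative bacteria by the **Tol-Pal** system.

Pal tethers the outer membrane to the cell wall and is nearly immobile when
bound to peptidoglycan (PG), yet it accumulates at the septum during
division. The mechanism modelled here is *mobilisation-and-capture*: the
periplasmic protein TolB binds Pal (blocking PG binding and mobilising it),
while inner-membrane TolQRA machines — homogeneously distributed in
non-dividing cells but septally localised in dividing cells — pull TolB back
across the cell wall, dissociating TolB–Pal complexes and depositing Pal
where the machines sit. This package implements the models and inference
needed to make that account quantitative, for modellers and microscopists
analysing FRAP line-profile data:

* a **two-compartment transport model** of TolB exchanging between the inner
  and outer periplasm,
  `∂B_out/∂t = D_out ∂²B_out/∂x² + αB_in − β(x)B_out` (and symmetrically for
  `B_in`), used to show that *localised* transport is less efficient than
  homogeneous transport and that exchange between mobility states speeds up
  FRAP recovery;
* the **four-species Tol-Pal model** for the TolB–Pal complex `C`, free TolB
  `B`, free Pal `P_f` and PG-bound Pal `P_b`, with mass-action binding
  (`αBP_f`), active (`β(x)C`) and spontaneous (`γC`) complex dissociation,
  and saturable PG binding (`k_on P_f(T−P_b) − k_off P_b`), on
  `x ∈ [−L/2, L/2]` with reflective boundaries;
* a **simulated-FRAP engine** integrating the coupled total + visible
  population systems (7 equations for Pal-labelled, 6 for TolB-labelled
  experiments) to produce kymographs matching the experimental acquisition
  protocols;
* **SpatialFRAP**: inference of a spatially varying effective diffusion
  coefficient `D_eff(x)` from a kymograph via the Fokker–Planck equation
  `∂c/∂t = ∂²(D_eff(x)c)/∂x²`, whose steady state fixes the shape of
  `D_eff(x)` (reciprocal of the pre-bleach profile) and whose recovery
  dynamics fix the scale;
* a **fitting pipeline** estimating the three unknown parameters — the
  diffusion coefficients `D_c` (complex) and `D_b` (free TolB), searched as
  `a = D_c − D_b`, `b = D_c/D_b` with bounds `a > 0`, `b > 1`, and the
  integrated dissociation strength `β₀` — by derivative-free minimisation of
  a weighted kymograph + `D_eff` mean-square error over dividing and
  non-dividing cells;
* a **synthetic-data generator** producing per-cell kymographs with length
  variability, pixelation and measurement noise, so the whole pipeline is
  testable without microscopy data.

## Worked example

Generate a synthetic dividing-cell Pal FRAP dataset and infer `D_eff(x)`:

```sh
tolpal synth --cell-type dividing --n-cells 2 --seed 1 --out d1
tolpal spatialfrap --kymo d1/average.tsv --out deff.json
```

which logs

```
[tolpal] synth wall=0.37s n_cells=2 cell_type=dividing seed=1
[tolpal] spatialfrap wall=0.00s scale=0.00110522 cost=0.0147357
```

The fitted `scale` is the spatial mean of `D_eff` in µm²/s: Pal in a dividing
cell moves with an effective diffusion coefficient of ≈1.1×10⁻³ µm²/s —
far below the diffusivity of the mobile TolB–Pal complex (6.8×10⁻³ µm²/s)
because most Pal is PG-bound at any instant — and `deff.json` contains the
full profile, with its characteristic valley at the septum (relative
position 0.5) flanked by faster regions.

The numbered scripts under `analysis/` run the complete study; each prints
its finding and writes tables under `results/`. For example:

```
$ python analysis/02_exchange_frap.py
frames to 90% recovery with exchange:    3
frames to 90% recovery without exchange: 30
speedup: 10.0x

$ python analysis/05_tolb_mobility.py
...
classification accuracy: 100%
TolB mean D_eff dividing:     5.560e-03
TolB mean D_eff non-dividing: 4.216e-03
ratio: 1.32
```

`analysis/03_fit_parameters.py` is the headline computation: it fits the
model to self-generated noiseless kymographs from a deliberately wrong
starting point and recovers `D_c`, `D_b` and `β₀` (a few minutes).

## Layout

```
src/tolpal/        library: model core, FRAP engine, SpatialFRAP, fitting,
                   synthetic data, workflows, CLI
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    modelling and numerical methods note
```
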