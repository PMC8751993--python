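# Methods

## Models

### Two-compartment TolB transport

The periplasm is split by the peptidoglycan (PG) layer into an outer and an
inner compartment with TolB concentrations `B_out(x,t)`, `B_in(x,t)` on the
cell axis `x ∈ [−L/2, L/2]`:

    ∂B_out/∂t = D_out ∂²B_out/∂x² + α B_in − β(x) B_out
    ∂B_in/∂t  = D_in  ∂²B_in/∂x²  − α B_in + β(x) B_out

with reflective boundaries and no production or degradation, so total TolB
is conserved. Inner→outer migration is uniform (rate `α`, 1/s);
outer→inner transport by TolQRA is the field `β(x)` (1/s) with integrated
strength `β₀ = ∫β dx`. Behaviour is governed by the dimensionless groups
`a = αL²/D_in`, `b = β₀/(αL)`, `d = D_out/D_in`; the dimensionless
constructor fixes `L = 1`, `D_in = 1`, mean total concentration 1.

### Four-species Tol-Pal model

Species: TolB–Pal complex `C` (outer periplasm), free TolB `B` (inner
periplasm), free Pal `P_f`, PG-bound Pal `P_b`. Reactions: TolB–Pal binding
`α B P_f`; active dissociation by TolQRA `β(x) C` (TolB returned to the
inner periplasm); spontaneous dissociation `γ C`; saturable PG binding
`k_on P_f (T − P_b) − k_off P_b`. `C`, `B`, `P_f` diffuse with `D_c`, `D_b`,
`D_f`; `P_b` is immobile. Total TolB (`∫C+B`) and total Pal (`∫C+P_f+P_b`)
are conserved.

Defaults (units; rationale):

| parameter | default | unit | origin |
|---|---|---|---|
| `D_c` | 0.0068 | µm²/s | fitted (complex diffusivity) |
| `D_b` | 0.0036 | µm²/s | fitted (free TolB, inner periplasm) |
| `D_f` | = `D_c` | µm²/s | Pal's mobility is limited by its lipoylated anchor, shared with the complex |
| `α` | 0.054 | 1/(µM·s) | in-vitro TolB–Pal binding kinetics |
| `β₀` | 17 | µm/s | fitted integrated TolQRA dissociation strength |
| `γ` | 0.006 | 1/s | in-vitro complex dissociation |
| `k_on` | 0.1 | 1/(µM·s) | estimate |
| `k_off` | 1.0 | 1/s | estimate |
| `T` | 320 | µM | PG binding-site concentration |
| `σ` | 0.08 | fraction of `L` | width of the septal TolQRA distribution |
| `L` | 4.0 / 2.8 | µm | mean dividing / non-dividing cell length |

Unit conventions that the literature leaves ambiguous, fixed here once:
`β₀` is quoted as a bare rate but enters only through `β(x) = β₀/L`
(homogeneous) or `β(x) = β₀·N(0,σ²)` (septal), so we treat `β(x)` as the
physical per-complex rate (1/s) and `β₀` as its spatial integral (µm·s⁻¹),
keeping the numeric value 17 with lengths in µm. `σ` is interpreted as a
fraction of cell length (std 0.08·L), since positions are reported on the
relative long axis; both conventions are configurable.

Absolute concentrations are not published (only copy numbers, ~60,000 Pal
vs ~6,000 TolB per cell), so the defaults `pal_total = 300 µM`,
`tolB_total = 30 µM` preserve the 10:1 ratio while keeping Pal just below
the PG-site concentration `T = 320 µM` — PG binding must be nearly but not
fully saturable, or bound Pal could not buffer septal accumulation. Both
totals are configurable; predictions reported here are ratios/orderings and
are insensitive to the absolute scale within a factor of a few.

The transport field `β(x)` comes in three discrete modes — `homogeneous`
(`β₀/L` everywhere), `point_sink` (all strength on the central node; exact
discrete delta, no smoothing parameter) and `truncated_normal` (normal
density truncated to the domain and renormalised so the *discrete* integral
is exactly `β₀`). Renormalising after truncation is a choice; it keeps the
total number of transport complexes identical across modes, which is what
the efficiency comparison requires.

## Discretisation and steady states

Space is discretised on `n` nodes spanning `[−L/2, L/2]` (`dx = L/(n−1)`)
with trapezoid control volumes (half-width at the ends). Diffusion is
applied in flux form, `J = −D ∂u/∂x` evaluated at faces with zero boundary
flux, so each conserved total is constant *to machine precision* in the
semi-discrete system; reaction terms are pointwise and conserve pairwise by
construction. Time integration uses LSODA with a banded Jacobian
(node-major species interleaving, bandwidth = number of species).

Steady states: the toy model is linear, so its steady state is solved
directly (least squares of the singular system plus the mass-normalisation
row). The Tol-Pal steady state is found by integrating from a uniform
initial condition (all TolB free, Pal at its PG-binding equilibrium
partition) for up to 10⁵ s with early exit, then polishing with a Newton
root solve in which two residual rows are replaced by the TolB/Pal mass
constraints; convergence requires `max|∂u/∂t| < 10⁻⁹ × pal_total` per
second, and species totals match their targets to 10⁻⁶ relative. The
steady state is independent of the (arbitrary) initial condition — the
uniform choice just shortens the transient. Default grids: n = 101 for
single simulations, n = 81 for prediction pipelines, n = 64 inside the fit
(grid-convergence tests show <1% sup-norm change on doubling n).

## Simulated FRAP

Bleaching is instantaneous, applied between the last pre-bleach and first
post-bleach frame; there is no photobleaching during acquisition, no
photophysics and no PSF convolution. The visible pool starts as the steady
state multiplied by a survival factor in [0,1] — either an idealised box
(depth 0.9 by default, optional error-function edges emulating the finite
bleach spot) or, when fitting data, the measured post/pre profile ratio.
The experimental 2D ROIs (1.5 × 0.2 µm Pal, 1.5 × 0.5 µm TolB) are
projected onto the axis: bleach width 1.5 µm, centred at mid-cell.

The coupled total + visible system is then integrated. Binding partners and
PG occupancy in the visible equations are the *total* fields (`B_T P_fv`,
`T − P_bT` for Pal labelling; `B_v P_fT` for TolB labelling): bleaching
destroys fluorophores, not chemistry, so bleached molecules still bind,
occupy PG sites and compete. This makes the visible subsystem linear, which
guarantees visible ≤ total pointwise and convergence of the visible profile
to (surviving fraction) × (steady profile); both are tested. Since the
total population starts at steady state it remains there, and Pal- and
TolB-labelled runs share identical total trajectories.

Acquisition protocols mirror the experiments: Pal 1 pre-bleach + 20
post-bleach frames at 30 s; TolB 2 + 75 at 2 s (the two pre-bleach frames
are averaged where a single profile is needed). The first post-bleach frame
is taken immediately after the bleach (elapsed time 0).

## SpatialFRAP

The observed total concentration is modelled by the Fokker–Planck equation
`∂c/∂t = ∂²(D_eff(x)c)/∂x²` with reflective boundaries, whose steady state
is ∝ `1/D_eff(x)`. Processing steps: drop the first and last two pixels
(polar signal artefacts), normalise each frame to sum 1, take the
(averaged) pre-bleach frame as the equilibrium profile, so
`D_eff(x) = scale × 1/prebleach(x)`; then fit the single scale by solving
the equation forward from the first post-bleach frame and minimising
10⁵ × the mean-square error against the post-bleach frames (the 10⁵ only
avoids very small numbers). The scalar fit is a derivative-free pattern
search from the initial guess 10⁻³ µm²/s, bounded to [10⁻⁶, 1] µm²/s; the
reported `scale` equals the spatial mean of `D_eff` in µm²/s.

The discrete operator uses the conservative second-difference form of
`∂²(Dc)/∂x²` with zero-flux closure, which conserves the frame sum exactly
and has the ∝1/D steady state *discretely*. Because `D_eff = s·shape` is
linear in the scale, `exp(tA)` is evaluated through one symmetric
eigendecomposition (the operator is similar to `diag(√shape)·M·diag(√shape)`)
and any candidate scale only rescales the eigenvalue exponents — the scale
fit therefore costs microseconds per evaluation. A kymograph with no bleach
contrast leaves the scale unidentifiable; such fits are flagged
`degenerate` rather than failed. For noisy data an optional moving-average
smoothing (window 3 px) is applied to the pre-bleach profile before taking
the reciprocal; it is off by default because it is unnecessary — and
slightly biasing — on noiseless input. With multiple pre-bleach frames
their average is used. Profiles from cells of different lengths are
compared on a common relative-axis grid.

## Parameter fitting

Free parameters: `a = D_c − D_b > 0`, `b = D_c/D_b > 1` (these bounds
enforce `D_c > D_b`, necessary for the observed septal TolB peak) and
`β₀ > 0`; everything else is fixed at the table above, with `D_f = D_c`.
For each candidate, Pal FRAP is simulated for both cell types (dividing:
L = 4 µm, truncated-normal `β`; non-dividing: L = 2.8 µm, homogeneous `β`)
using the *data's* frame times and measured bleach profile, resampled to
the data's pixel grid; the simulated kymograph is preprocessed identically
to the data, and its `D_eff` is computed by the same SpatialFRAP code —
like is compared with like throughout. Cost =
`10⁵·(MSE_kym,div + MSE_kym,nondiv) + 10⁷·(MSE_deff,div + MSE_deff,nondiv)`;
simulation failures receive a large finite penalty.

Minimisation is derivative-free and fully deterministic: a compass/pattern
search in `(log a, log(b−1), log β₀)` — so the bounds hold for every
evaluated point and steps are relative — polling all six directions per
iteration (mesh ×2 on success, ×0.5 on failure), followed by a short
Nelder–Mead simplex refinement. The refinement exists because the cost
surface has a curved valley coupling `b` and `β₀` along which axis-aligned
polling stalls; the simplex stage tracks the valley to its bottom. Default
initial point `(a, b, β₀) = (0.003, 2, 10)`; with the default budget
(250 poll + 150 simplex evaluations) a recovery fit on noiseless
self-generated data returns `D_c` within ~0.5%, `D_b` within ~2% and `β₀`
within ~10% of the generating values in a few minutes on one CPU.

Predictions reuse the fitted parameters unchanged: TolA deletion sets
`β₀ = 0` (no active dissociation; the spatial mode is then irrelevant);
the TolB-binding mutant sets `α = 0` while *keeping* TolB mass, matching
the biochemical lesion (TolB present but unable to bind Pal); TolA
overexpression is modelled purely as a reduction of available TolB
(fraction of `tolB_total`), with no explicit TolA species. TolB-labelled
FRAP bleaches `C` and `B` instead of the Pal states.

## Synthetic data

Each synthetic cell draws a length from a truncated normal
(mean 4.0/2.8 µm, CV 0.1, ±3 CV bounds), simulates the labelled-species
FRAP at the ground-truth parameters, resamples to 0.05 µm pixels and
applies multiplicative Gaussian noise (CV 0.02 by default, clipped at
−0.99). Multiplicative noise is chosen over Poisson because frame
normalisation makes the analysis scale-free, so only relative noise
matters; a Poisson mode is available behind the `noise_model` switch.
Datasets default to 30 cells; averages are computed frame-wise on a 64-point
relative-position grid. An optional polar edge attenuation (off by default)
emulates the low-signal pole pixels that motivate the 2-pixel trim. Cells
with polar foci, which the experimental TolB analysis excluded, are not
emulated. Everything is deterministic given (seed, cell index), and
different seeds change only noise and length draws, never the noiseless
signal.

What the generator does *not* emulate — 2D imaging, point-spread blur,
acquisition bleaching, segmentation error, cell-cycle heterogeneity in
`β(x)` — bounds what passing tests show: they validate the inference
machinery and the model's internal consistency, not the microscope model.

## Numerical choices and limitations

* Integration tolerances: rtol 10⁻⁸ (10⁻¹⁰ in conservation tests), absolute
  tolerance scaled to the concentration magnitude.
* Even-`n` grids have no centre node; the point sink splits across the two
  middle nodes, and "central maximum" checks use odd `n`.
* The point sink and a narrow truncated normal (σ → dx) agree to ~1% in
  outer-compartment mass at n = 401, converging linearly in σ.
* The model is strictly 1D with reflective ends: no membrane curvature, no
  explicit TolA dynamics (TolA enters only through `β(x)`), no stochastic
  single-molecule effects.
* Identifiability of `β₀` is the weakest of the three fitted parameters
  (the cost is flattest along it), which is why its recovery tolerance is
  wider; with noisy data (2% multiplicative), recovered diffusivities stay
  within ~50% over seeds while `β₀` can wander further.
* SpatialFRAP assumes the effective-diffusion regime; on reaction-diffusion
  kymographs it returns the *effective* mobility of the labelled pool,
  which is the quantity the experimental analysis reports, not any single
  species' diffusivity.
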