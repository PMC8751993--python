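"""High-level analysis drivers.

Each function runs one of the package's headline computations end to end —
generating its own synthetic inputs — and returns plain dictionaries of
scalars/arrays.  The numbered scripts under ``analysis/`` and the acceptance
machinery are thin wrappers over these.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fitting import (
    FitConfig,
    FitData,
    MutantSpec,
    fit,
    predict_mutant,
    predict_tolB_frap,
)
from .frap import FrapProtocol, synthetic_bleach_function, toy_simulate_frap
from .kymo import Kymograph
from .model import (
    SpeciesTotals,
    TolPalParams,
    ToyParams,
    make_grid,
    make_transport_profile,
    tolpal_steady_state,
    toy_steady_state,
)
from .spatialfrap import fokker_planck_solve, spatialfrap
from .synth import SyntheticConfig, generate_dataset

TABLE_PARAMS = TolPalParams()          # the fitted/literature values
A_TRUE = TABLE_PARAMS.D_c - TABLE_PARAMS.D_b
B_TRUE = TABLE_PARAMS.D_c / TABLE_PARAMS.D_b
BETA0_TRUE = TABLE_PARAMS.beta0


def noiseless_average_kymographs(seed: int = 1) -> FitData:
    """Noiseless dividing/non-dividing Pal averages at the reference truth."""
    kymos = {}
    for ct in ("dividing", "nondividing"):
        cfg = SyntheticConfig(cell_type=ct, n_cells=1, length_cv=0.0,
                              noise_model="none", noise_cv=0.0, seed=seed)
        kymos[ct] = generate_dataset(cfg).average
    return FitData(kymo_div=kymos["dividing"],
                   kymo_nondiv=kymos["nondividing"])


def parameter_recovery(seed: int = 1, max_evals: int = 250,
                       polish_evals: int = 150) -> dict:
    """Recover (D_c, D_b, beta0) from self-generated noiseless data.

    The fit starts from the truth perturbed by (x2, x1.5, x0.5) on
    (a, b, beta0), mimicking ignorance of the true values.
    """
    data = noiseless_average_kymographs(seed=seed)
    config = FitConfig(
        initial=(A_TRUE * 2.0, 1.0 + (B_TRUE - 1.0) * 1.5, BETA0_TRUE * 0.5),
        max_evals=max_evals, polish_evals=polish_evals)
    result = fit(data, config)
    return {
        "fit": result,
        "D_c": result.D_c, "D_b": result.D_b, "beta0": result.beta0,
        "D_c_rel_err": abs(result.D_c - TABLE_PARAMS.D_c) / TABLE_PARAMS.D_c,
        "D_b_rel_err": abs(result.D_b - TABLE_PARAMS.D_b) / TABLE_PARAMS.D_b,
        "beta0_rel_err": abs(result.beta0 - BETA0_TRUE) / BETA0_TRUE,
    }


def transport_efficiency_grid(n_each: int = 5, n_nodes: int = 61) -> dict:
    """Outer-compartment mass, localised vs homogeneous transport.

    Scans a log-spaced grid of the dimensionless parameters
    a in [1, 100], b in [0.1, 100], d in [0.02, 5].
    """
    rows = []
    for a in np.logspace(0, 2, n_each):
        for b in np.logspace(-1, 2, n_each):
            for d in np.logspace(np.log10(0.02), np.log10(5.0), n_each):
                hom = toy_steady_state(
                    ToyParams.from_dimensionless(a, b, d), n=n_nodes)
                loc = toy_steady_state(
                    ToyParams.from_dimensionless(a, b, d, mode="point_sink"),
                    n=n_nodes)
                rows.append((a, b, d, hom.outer_fraction, loc.outer_fraction))
    arr = np.array(rows)
    margins = arr[:, 4] - arr[:, 3]
    return {"rows": arr, "min_margin": float(margins.min()),
            "all_localised_ge": bool(np.all(margins >= -1e-9))}


def exchange_recovery_speed(n_nodes: int = 101) -> dict:
    """Simulated FRAP with vs without exchange at matched steady states.

    Uses the dimensionless conditions d = 0.02 and, with transport, a = 50,
    b = 1; reports the first post-bleach frame at which the bleached region
    reaches 90% of its recovered asymptote.
    """
    g = make_grid(1.0, n_nodes)
    p_with = ToyParams.from_dimensionless(a=50.0, b=1.0, d=0.02)
    ss = toy_steady_state(p_with, n=n_nodes)
    protocol = FrapProtocol(n_prebleach=1, n_postbleach=120, dt=0.05,
                            bleach_width=0.375, bleach_depth=0.9)
    bleach = synthetic_bleach_function(protocol, g, edge_sigma=0.02)
    k_with = toy_simulate_frap(p_with, p_with.transport_profile(g), protocol,
                               bleach, steady=ss)
    p_wo = ToyParams(D_out=0.02, D_in=1.0, alpha=1e-12, beta0=0.0, L=1.0)
    k_wo = toy_simulate_frap(p_wo, make_transport_profile("homogeneous", 0.0,
                                                          g),
                             protocol, bleach, steady=ss)
    pre = ss.B_out + ss.B_in
    roi = np.abs(g.x) <= protocol.bleach_width / 2

    def frames_to_90pct(kymo: Kymograph) -> float:
        surviving = g.integrate(kymo.values[1]) / g.integrate(pre)
        target = 0.9 * surviving * pre[roi].sum()
        signal = kymo.values[1:, roi].sum(axis=1)
        hit = np.nonzero(signal >= target)[0]
        return float(hit[0]) if hit.size else np.inf

    t_with = frames_to_90pct(k_with)
    t_without = frames_to_90pct(k_wo)
    return {"frames_with": t_with, "frames_without": t_without,
            "speedup": t_without / max(t_with, 1.0)}


def tolb_peak_condition(pairs=None, n_nodes: int = 81) -> dict:
    """Septal peak in total TolB iff the complex outdiffuses free TolB."""
    if pairs is None:
        pairs = [(0.0068, 0.0036), (0.0068, 0.0063), (0.0050, 0.0020),
                 (0.0036, 0.0068), (0.0060, 0.0066), (0.0020, 0.0050)]
    totals = SpeciesTotals()
    results = []
    for D_c, D_b in pairs:
        params = replace(TABLE_PARAMS, D_c=D_c, D_b=D_b)
        grid = make_grid(4.0, n_nodes)
        beta = params.transport_profile(grid, "truncated_normal")
        state = tolpal_steady_state(params, beta, totals)
        prof = state.total_tolB_profile()
        peaked = bool(prof[grid.n // 2] > prof[grid.n // 8])
        results.append({"D_c": D_c, "D_b": D_b, "peaked": peaked,
                        "expected": D_c > D_b})
    correct = sum(r["peaked"] == r["expected"] for r in results)
    return {"cases": results, "accuracy": correct / len(results)}


def mutant_predictions(n_nodes: int = 81) -> dict:
    """Pal mobility in the two loss-of-function mutants vs wild type."""
    totals = SpeciesTotals()
    _, wt_div = predict_mutant(TABLE_PARAMS, totals, MutantSpec("wild_type"),
                               cell_type="dividing", n=n_nodes)
    _, wt_nondiv = predict_mutant(TABLE_PARAMS, totals,
                                  MutantSpec("wild_type"),
                                  cell_type="nondividing", n=n_nodes)
    flank = float(wt_div.D_eff[np.abs(wt_div.positions - 0.5) > 0.2].mean())
    out = {"wt_dividing_mean": wt_div.mean,
           "wt_dividing_flank": flank,
           "wt_nondividing_mean": wt_nondiv.mean,
           "profiles": {"wt_dividing": wt_div, "wt_nondividing": wt_nondiv}}
    for label, kind in (("delta_tolA", "delta_tolA"),
                        ("delta_tolB_binding", "delta_tolB_binding")):
        _, prof = predict_mutant(TABLE_PARAMS, totals, MutantSpec(kind),
                                 cell_type="dividing", n=n_nodes)
        out[f"{label}_mean"] = prof.mean
        out[f"{label}_vs_nondiv"] = abs(prof.mean - wt_nondiv.mean) \
            / wt_nondiv.mean
        out["profiles"][label] = prof
    return out


def tolb_mobility_prediction(n_nodes: int = 81) -> dict:
    """TolB-labelled FRAP: effective diffusion in dividing vs non-dividing."""
    preds = predict_tolB_frap(TABLE_PARAMS, SpeciesTotals(), n=n_nodes)
    div, nondiv = preds["dividing"][1], preds["nondividing"][1]
    return {"dividing_mean": div.mean, "nondividing_mean": nondiv.mean,
            "ratio": div.mean / nondiv.mean,
            "profiles": {"dividing": div, "nondividing": nondiv}}


def tolb_reduction_sweep(fractions=(1.0, 0.5, 0.25, 0.1),
                         n_nodes: int = 81) -> dict:
    """Mean Pal mobility as TolB is titrated away (TolA overexpression)."""
    totals = SpeciesTotals()
    means = []
    for frac in fractions:
        _, prof = predict_mutant(TABLE_PARAMS, totals,
                                 MutantSpec("tolB_reduction",
                                            tolB_fraction=frac),
                                 cell_type="dividing", n=n_nodes)
        means.append(prof.mean)
    monotone = all(m1 > m2 for m1, m2 in zip(means, means[1:]))
    return {"fractions": list(fractions), "means": means,
            "monotone_decreasing": bool(monotone)}


def spatialfrap_selfinversion(seed: int = 1, n_pixels: int = 60,
                              noise_cv: float = 0.02,
                              n_seeds: int = 5) -> dict:
    """Forward-simulate Fokker-Planck kymographs and invert them.

    Reports the sup-norm relative error for noiseless constant and varying
    diffusivity fields, and the median (over ``n_seeds`` noise realisations)
    mean relative error under multiplicative noise.
    """
    dx = 0.05
    x = np.arange(n_pixels) * dx
    base = 1.0 + 0.8 * np.sin(np.linspace(0, np.pi, n_pixels)) ** 2
    fields = {"constant": np.full(n_pixels, 0.004),
              "varying": 0.003 * base / base.mean()}
    times = 30.0 * np.arange(20)
    mid = x.mean()
    roi = (x > mid - 0.75) & (x < mid + 0.75)

    def make_kymo(D, rng=None):
        css = (1.0 / D) / (1.0 / D).sum()
        c0 = css * (1.0 - 0.9 * roi)
        frames = fokker_planck_solve(D, c0, times, dx)
        full = np.vstack([css[None, :], frames])
        if rng is not None:
            full = np.clip(full * (1.0 + rng.normal(0, noise_cv, full.shape)),
                           1e-9, None)
        # sacrificial pole pixels, discarded by the preprocessing trim
        full = np.hstack([full[:, :1] * 0.5, full[:, :1] * 0.5, full,
                          full[:, -1:] * 0.5, full[:, -1:] * 0.5])
        return Kymograph(times=30.0 * np.arange(full.shape[0]),
                         positions=np.arange(full.shape[1]) * dx,
                         values=full, n_prebleach=1, pixel_size=dx)

    out = {}
    for name, D in fields.items():
        prof = spatialfrap(make_kymo(D))
        out[f"{name}_sup_err"] = float(np.max(np.abs(prof.D_eff - D) / D))
    noisy_errs = []
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, k])
        prof = spatialfrap(make_kymo(fields["varying"], rng=rng),
                           smooth_window=3)
        noisy_errs.append(float(np.mean(np.abs(prof.D_eff - fields["varying"])
                                        / fields["varying"])))
    out["noisy_median_err"] = float(np.median(noisy_errs))
    out["noisy_errs"] = noisy_errs
    return out
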