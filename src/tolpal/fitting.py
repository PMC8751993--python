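"""Parameter estimation and model predictions.

The three unknown parameters of the Tol-Pal model — the diffusion
coefficients of the TolB-Pal complex (D_c) and of free TolB (D_b), and the
integrated TolQRA dissociation strength beta0 — are estimated by fitting
simulated Pal FRAP experiments to dividing and non-dividing kymographs and
their SpatialFRAP effective-diffusion profiles.  D_c and D_b are searched
through the combinations

    a = D_c - D_b,   b = D_c / D_b,

with bounds a > 0 and b > 1, which enforce D_c > D_b (required for the
observed septal accumulation of total TolB).  The cost is a weighted sum of
mean-square errors: 1e5 x (kymograph MSEs) + 1e7 x (D_eff MSEs), summed over
the two cell types, minimised by deterministic pattern search.

The same machinery generates the model's predictions: Pal mobility in the
delta-tolA and TolB-binding-deficient mutants, TolB-labelled FRAP, and the
effect of titrating TolB away from Pal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .frap import FrapProtocol, BleachFunction, simulate_frap
from .kymo import Kymograph
from .model import (
    SpeciesTotals,
    TolPalParams,
    make_grid,
    tolpal_steady_state,
)
from .optimize import pattern_search
from .spatialfrap import DeffProfile, preprocess_kymograph, spatialfrap
from .frap import synthetic_bleach_function

__all__ = [
    "FitConfig",
    "FitData",
    "FitResult",
    "MutantSpec",
    "params_from_ab",
    "ab_from_params",
    "fit_cost",
    "fit",
    "predict_mutant",
    "predict_tolB_frap",
]


# ---------------------------------------------------------------------------
# Parameterisation
# ---------------------------------------------------------------------------

def params_from_ab(a: float, b: float, beta0: float,
                   fixed: TolPalParams | None = None) -> TolPalParams:
    """Build model parameters from the fit coordinates (a, b, beta0).

    ``D_b = a/(b-1)``, ``D_c = a b/(b-1)``; free Pal diffuses like the
    complex (D_f = D_c).  All other rates come from ``fixed`` (defaults).
    """
    if not (a > 0):
        raise ValidationError(f"bound violated: a must be > 0, got {a}")
    if not (b > 1):
        raise ValidationError(f"bound violated: b must be > 1, got {b}")
    if not (beta0 > 0):
        raise ValidationError(f"bound violated: beta0 must be > 0, got {beta0}")
    fixed = fixed if fixed is not None else TolPalParams()
    D_b = a / (b - 1.0)
    D_c = a * b / (b - 1.0)
    return replace(fixed, D_c=D_c, D_b=D_b, D_f=None, beta0=beta0)


def ab_from_params(params: TolPalParams) -> tuple[float, float]:
    """Inverse map: (a, b) = (D_c - D_b, D_c / D_b)."""
    return params.D_c - params.D_b, params.D_c / params.D_b


# ---------------------------------------------------------------------------
# Configuration and data containers
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    w_kym: float = 1e5
    w_deff: float = 1e7
    L_div: float = 4.0
    L_nondiv: float = 2.8
    n_grid: int = 64
    fixed: TolPalParams = field(default_factory=TolPalParams)
    totals: SpeciesTotals = field(default_factory=SpeciesTotals)
    initial: tuple[float, float, float] = (0.003, 2.0, 10.0)  # (a, b, beta0)
    step0: float = 0.5           # initial mesh in log coordinates
    tol: float = 1e-6            # mesh convergence threshold
    max_evals: int = 250
    polish_evals: int = 150      # simplex polish budget (0 disables)
    trim: int = 2
    smooth_window: int | None = None
    penalty: float = 1e6         # cost assigned to failed simulations


@dataclass
class FitData:
    """Dividing and non-dividing Pal FRAP kymographs (plus optional D_eff).

    If the effective-diffusion profiles are not supplied they are computed
    from the kymographs with SpatialFRAP, mirroring how the model output is
    processed inside the cost function.
    """

    kymo_div: Kymograph
    kymo_nondiv: Kymograph
    deff_div: DeffProfile | None = None
    deff_nondiv: DeffProfile | None = None

    def prepared(self, config: FitConfig) -> dict:
        out = {}
        for name, kym, deff in (("div", self.kymo_div, self.deff_div),
                                ("nondiv", self.kymo_nondiv, self.deff_nondiv)):
            proc = preprocess_kymograph(kym, trim=config.trim)
            if deff is None:
                deff = spatialfrap(kym, trim=config.trim,
                                   smooth_window=config.smooth_window)
            pre = kym.prebleach_profile()
            post0 = kym.values[kym.n_prebleach]
            factor = np.clip(post0 / pre, 0.0, 1.0)
            out[name] = {
                "kymo": kym,
                "proc": proc,
                "deff": deff,
                "bleach_rel": (kym.rel_positions, factor),
            }
        return out


@dataclass
class FitResult:
    a: float
    b: float
    beta0: float
    cost: float
    components: dict
    n_evals: int
    converged: bool
    improved: bool
    trace: list
    config: FitConfig | None = None

    @property
    def D_c(self) -> float:
        return self.a * self.b / (self.b - 1.0)

    @property
    def D_b(self) -> float:
        return self.a / (self.b - 1.0)

    def params(self) -> TolPalParams:
        fixed = self.config.fixed if self.config else None
        return params_from_ab(self.a, self.b, self.beta0, fixed=fixed)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "beta0": self.beta0,
            "D_c": self.D_c, "D_b": self.D_b, "cost": self.cost,
            "components": self.components, "n_evals": self.n_evals,
            "converged": self.converged, "improved": self.improved,
        }


# ---------------------------------------------------------------------------
# Cost function
# ---------------------------------------------------------------------------

def _simulate_cell_type(params: TolPalParams, config: FitConfig, name: str,
                        prep: dict, totals: SpeciesTotals) -> Kymograph:
    """Pal FRAP simulation matched to one data kymograph's acquisition."""
    L = config.L_div if name == "div" else config.L_nondiv
    mode = "truncated_normal" if name == "div" else "homogeneous"
    grid = make_grid(L, config.n_grid)
    beta = params.transport_profile(grid, mode)
    kym = prep["kymo"]
    post_times = kym.times[kym.n_prebleach:]
    dt = float(np.mean(np.diff(post_times)))
    protocol = FrapProtocol(n_prebleach=kym.n_prebleach,
                            n_postbleach=post_times.size, dt=dt,
                            bleach_width=1.5, labelled="pal")
    rel_data, factor_data = prep["bleach_rel"]
    grid_rel = (grid.x - grid.x[0]) / (grid.x[-1] - grid.x[0])
    factor = np.interp(grid_rel, rel_data, factor_data)
    bleach = BleachFunction(grid, np.clip(factor, 0.0, 1.0))
    sim = simulate_frap(params, beta, totals, protocol, bleach)
    return sim.resampled(kym.rel_positions)


def fit_cost(a: float, b: float, beta0: float, data: FitData | dict,
             config: FitConfig | None = None,
             return_components: bool = False):
    """Weighted cost of one (a, b, beta0) candidate against both cell types.

    Simulation failures yield the (large, finite) configured penalty so the
    optimiser can route around pathological parameter regions.
    """
    config = config or FitConfig()
    prepared = data.prepared(config) if isinstance(data, FitData) else data
    try:
        params = params_from_ab(a, b, beta0, fixed=config.fixed)
    except ValidationError:
        return (config.penalty, {}) if return_components else config.penalty
    comps = {}
    total = 0.0
    for name, prep in prepared.items():
        try:
            sim = _simulate_cell_type(params, config, name, prep,
                                      config.totals)
            sim_proc = preprocess_kymograph(sim, trim=config.trim)
            mse_k = float(np.mean((sim_proc.values - prep["proc"].values) ** 2))
            sim_deff = spatialfrap(sim, trim=config.trim)
            mse_d = float(np.mean((sim_deff.D_eff - prep["deff"].D_eff) ** 2))
        except Exception:  # numerical failure at this candidate
            comps[name] = {"kymo_mse": None, "deff_mse": None}
            total += config.penalty
            continue
        comps[name] = {"kymo_mse": mse_k, "deff_mse": mse_d}
        total += config.w_kym * mse_k + config.w_deff * mse_d
    return (total, comps) if return_components else total


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------

def fit(data: FitData, config: FitConfig | None = None) -> FitResult:
    """Estimate (a, b, beta0) by pattern search in log coordinates.

    The search runs over (log a, log(b-1), log beta0) so every evaluated
    point satisfies a > 0, b > 1, beta0 > 0 by construction.  Compass
    searches stall on the curved valley that couples b and beta0, so the
    pattern-search result is refined with a short (deterministic)
    Nelder-Mead simplex stage; with a fixed configuration the whole
    procedure is deterministic.
    """
    from scipy import optimize as _sopt

    config = config or FitConfig()
    prepared = data.prepared(config)
    a0, b0, beta00 = config.initial
    u0 = np.array([np.log(a0), np.log(b0 - 1.0), np.log(beta00)])

    def cost_of_log(u):
        a = float(np.exp(u[0]))
        b = 1.0 + float(np.exp(u[1]))
        beta0 = float(np.exp(u[2]))
        return fit_cost(a, b, beta0, prepared, config)

    res = pattern_search(cost_of_log, u0, step0=config.step0, tol=config.tol,
                         max_evals=config.max_evals)
    x, n_evals, trace = res.x, res.n_evals, res.trace
    if config.polish_evals > 0:
        pol = _sopt.minimize(cost_of_log, x, method="Nelder-Mead",
                             options={"maxfev": config.polish_evals,
                                      "xatol": 1e-4, "fatol": 1e-10})
        if pol.fun <= res.fun:
            x = pol.x
        n_evals += pol.nfev
        trace = trace + [(n_evals, float(min(pol.fun, res.fun)))]
    a = float(np.exp(x[0]))
    b = 1.0 + float(np.exp(x[1]))
    beta0 = float(np.exp(x[2]))
    total, comps = fit_cost(a, b, beta0, prepared, config,
                            return_components=True)
    return FitResult(a=a, b=b, beta0=beta0, cost=total, components=comps,
                     n_evals=n_evals, converged=res.converged,
                     improved=res.improved, trace=trace, config=config)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

MUTANT_KINDS = ("wild_type", "delta_tolA", "delta_tolB_binding",
                "tolB_reduction")


@dataclass(frozen=True)
class MutantSpec:
    """A genetic/expression perturbation realised in the model.

    delta_tolA removes active dissociation (beta0 = 0: no functional TolQRA
    pulling); delta_tolB_binding abolishes TolB-Pal complex formation
    (alpha = 0) while keeping TolB levels; tolB_reduction scales the total
    TolB pool (emulating sequestration by excess TolA).
    """

    kind: str = "wild_type"
    tolB_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in MUTANT_KINDS:
            raise ValidationError(f"unknown mutant kind {self.kind!r}; "
                                  f"expected one of {MUTANT_KINDS}")
        if self.kind == "tolB_reduction" and not (0 < self.tolB_fraction <= 1):
            raise ValidationError("tolB_fraction must lie in (0, 1]")


def _apply_mutant(params: TolPalParams, totals: SpeciesTotals,
                  spec: MutantSpec) -> tuple[TolPalParams, SpeciesTotals]:
    if spec.kind == "delta_tolA":
        return replace(params, beta0=0.0), totals
    if spec.kind == "delta_tolB_binding":
        return replace(params, alpha=0.0), totals
    if spec.kind == "tolB_reduction":
        return params, replace(totals,
                               tolB_total=totals.tolB_total * spec.tolB_fraction)
    return params, totals


def _frap_and_deff(params: TolPalParams, totals: SpeciesTotals,
                   protocol: FrapProtocol, mode: str, L: float, n: int,
                   bleach_edge_sigma: float) -> tuple[Kymograph, DeffProfile]:
    grid = make_grid(L, n)
    beta = params.transport_profile(grid, mode)
    bleach = synthetic_bleach_function(protocol, grid,
                                       edge_sigma=bleach_edge_sigma)
    kymo = simulate_frap(params, beta, totals, protocol, bleach)
    return kymo, spatialfrap(kymo)


def predict_mutant(params: TolPalParams, totals: SpeciesTotals,
                   spec: MutantSpec,
                   protocol: FrapProtocol | None = None,
                   cell_type: str = "dividing", L: float | None = None,
                   n: int = 81, bleach_edge_sigma: float = 0.05,
                   ) -> tuple[Kymograph, DeffProfile]:
    """Predicted Pal FRAP kymograph and D_eff profile for a perturbation.

    Uses the fitted wild-type parameters with only the mutant's defining
    change applied, then runs the standard FRAP + SpatialFRAP pipeline.
    For delta_tolA the transport profile is irrelevant (beta0 = 0).
    """
    protocol = protocol or FrapProtocol.pal_default()
    mparams, mtotals = _apply_mutant(params, totals, spec)
    if cell_type == "dividing":
        mode, L = "truncated_normal", (4.0 if L is None else L)
    elif cell_type == "nondividing":
        mode, L = "homogeneous", (2.8 if L is None else L)
    else:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    if mparams.beta0 == 0.0:
        mode = "homogeneous"   # localisation of an absent activity is moot
    return _frap_and_deff(mparams, mtotals, protocol, mode, L, n,
                          bleach_edge_sigma)


def predict_tolB_frap(params: TolPalParams, totals: SpeciesTotals,
                      protocol: FrapProtocol | None = None,
                      n: int = 81, bleach_edge_sigma: float = 0.05,
                      L_div: float = 4.0, L_nondiv: float = 2.8) -> dict:
    """TolB-labelled FRAP prediction for dividing and non-dividing cells.

    Returns ``{"dividing": (Kymograph, DeffProfile), "nondividing": ...}``.
    """
    protocol = protocol or FrapProtocol.tolb_default()
    if protocol.labelled != "tolb":
        raise ValidationError("protocol must label TolB")
    return {
        "dividing": _frap_and_deff(params, totals, protocol,
                                   "truncated_normal", L_div, n,
                                   bleach_edge_sigma),
        "nondividing": _frap_and_deff(params, totals, protocol,
                                      "homogeneous", L_nondiv, n,
                                      bleach_edge_sigma),
    }
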