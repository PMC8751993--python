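"""In-silico FRAP: bleach functions and coupled total/visible simulations.

A FRAP experiment is simulated in two phases.  First the model is run to its
steady state, which supplies the pre-bleach frame(s).  Bleaching is treated as
instantaneous: the visible pool of the labelled species is the steady state
multiplied by a per-position survival factor, while the *total* populations
are unaffected (photobleaching destroys fluorophores, not chemistry).  The
coupled total + visible system is then integrated; binding terms in the
visible equations use the total concentrations of the partner species and of
occupied peptidoglycan sites, which makes the visible subsystem linear and
guarantees visible <= total throughout.

For Pal-mCherry the visible pool spans complexes, free Pal and bound Pal
(7 coupled equations); for TolB-mCherry it spans complexes and inner-periplasm
TolB (6 equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import IntegrationError, ValidationError
from .kymo import Kymograph
from .model import (
    Grid1D,
    SpeciesTotals,
    TolPalParams,
    TolPalState,
    ToyParams,
    ToyProfiles,
    TransportProfile,
    _integrate_banded,
    _laplacian,
    _pack,
    _unpack,
    tolpal_steady_state,
    toy_steady_state,
)

__all__ = [
    "FrapProtocol",
    "BleachFunction",
    "bleach_function_from_profiles",
    "synthetic_bleach_function",
    "simulate_frap",
    "toy_simulate_frap",
]


@dataclass(frozen=True)
class FrapProtocol:
    """Acquisition protocol of a FRAP experiment.

    Defaults follow the experimental protocols: Pal-mCherry uses 1 pre-bleach
    frame and 20 post-bleach frames at 30 s intervals; TolB-mCherry uses 2
    pre-bleach and 75 post-bleach frames at 2 s.  The 2D bleach ROI
    (1.5 x 0.2 um for Pal, 1.5 x 0.5 um for TolB) is projected onto the long
    axis, giving a 1.5 um bleach width centred on the septum.
    """

    n_prebleach: int = 1
    n_postbleach: int = 20
    dt: float = 30.0
    bleach_width: float = 1.5
    bleach_centre: float = 0.0
    bleach_depth: float = 0.9
    labelled: str = "pal"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("frame interval dt must be positive")
        if not (0 < self.bleach_depth <= 1):
            raise ValidationError("bleach_depth must lie in (0, 1]")
        if self.labelled not in ("pal", "tolb"):
            raise ValidationError(f"unknown labelled species {self.labelled!r}")

    @classmethod
    def pal_default(cls, **kw) -> "FrapProtocol":
        return cls(**{**dict(n_prebleach=1, n_postbleach=20, dt=30.0,
                             bleach_width=1.5, labelled="pal"), **kw})

    @classmethod
    def tolb_default(cls, **kw) -> "FrapProtocol":
        return cls(**{**dict(n_prebleach=2, n_postbleach=75, dt=2.0,
                             bleach_width=1.5, bleach_depth=0.9,
                             labelled="tolb"), **kw})

    def frame_times(self) -> np.ndarray:
        """Wall-clock frame times with the first frame at t = 0.

        The bleach occurs between frames ``n_prebleach - 1`` and
        ``n_prebleach``; the first post-bleach frame is acquired immediately
        after the bleach.
        """
        return self.dt * np.arange(self.n_prebleach + self.n_postbleach)


@dataclass(frozen=True)
class BleachFunction:
    """Per-node multiplicative survival fraction in [0, 1]."""

    grid: Grid1D
    factor: np.ndarray = field(repr=False)

    def __post_init__(self):
        if np.any(self.factor < 0) or np.any(self.factor > 1):
            raise ValidationError("bleach factors must lie in [0, 1]")


def bleach_function_from_profiles(pre: np.ndarray, post: np.ndarray,
                                  grid: Grid1D | None = None) -> BleachFunction:
    """Bleach function from data: post/pre line-profile ratio, clipped to [0,1]."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValidationError("pre- and post-bleach profiles differ in length")
    if np.any(pre <= 0):
        raise ValidationError("pre-bleach profile must be strictly positive")
    factor = np.clip(post / pre, 0.0, 1.0)
    return BleachFunction(grid=grid, factor=factor)


def synthetic_bleach_function(protocol: FrapProtocol, grid: Grid1D,
                              edge_sigma: float = 0.0) -> BleachFunction:
    """Idealised bleach: factor = 1 - depth inside the ROI, 1 outside.

    ``edge_sigma`` (um) smooths the ROI edges with an error-function profile,
    emulating the finite focal spot of the bleaching laser.
    """
    lo = protocol.bleach_centre - protocol.bleach_width / 2.0
    hi = protocol.bleach_centre + protocol.bleach_width / 2.0
    if lo < grid.x[0] - 1e-9 or hi > grid.x[-1] + 1e-9:
        raise ValidationError("bleach ROI extends outside the cell")
    if edge_sigma > 0:
        box = 0.5 * (special.erf((grid.x - lo) / (np.sqrt(2) * edge_sigma))
                     - special.erf((grid.x - hi) / (np.sqrt(2) * edge_sigma)))
    else:
        box = ((grid.x >= lo) & (grid.x <= hi)).astype(float)
    factor = 1.0 - protocol.bleach_depth * box
    return BleachFunction(grid=grid, factor=np.clip(factor, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Coupled total/visible integration
# ---------------------------------------------------------------------------

def _frap_rhs_pal(arr, params, beta, grid):
    """(7, n) rhs: totals (C, B, P_f, P_b) + visible (C_v, P_fv, P_bv)."""
    C, B, Pf, Pb, Cv, Pfv, Pbv = arr
    out = np.empty_like(arr)
    bind = params.alpha * B * Pf
    dis = (beta + params.gamma) * C
    pg_on = params.k_on * Pf * (params.T - Pb)
    pg_off = params.k_off * Pb
    out[0] = _laplacian(C, params.D_c, grid) + bind - dis
    out[1] = _laplacian(B, params.D_b, grid) - bind + dis
    out[2] = (_laplacian(Pf, params.D_free_pal, grid) - bind + dis
              - pg_on + pg_off)
    out[3] = pg_on - pg_off
    # Visible Pal: binding partner TolB and PG occupancy come from the totals.
    bind_v = params.alpha * B * Pfv
    dis_v = (beta + params.gamma) * Cv
    pg_on_v = params.k_on * Pfv * (params.T - Pb)
    pg_off_v = params.k_off * Pbv
    out[4] = _laplacian(Cv, params.D_c, grid) + bind_v - dis_v
    out[5] = (_laplacian(Pfv, params.D_free_pal, grid) - bind_v + dis_v
              - pg_on_v + pg_off_v)
    out[6] = pg_on_v - pg_off_v
    return out


def _frap_rhs_tolb(arr, params, beta, grid):
    """(6, n) rhs: totals (C, B, P_f, P_b) + visible (C_v, B_v)."""
    C, B, Pf, Pb, Cv, Bv = arr
    out = np.empty_like(arr)
    bind = params.alpha * B * Pf
    dis = (beta + params.gamma) * C
    pg_on = params.k_on * Pf * (params.T - Pb)
    pg_off = params.k_off * Pb
    out[0] = _laplacian(C, params.D_c, grid) + bind - dis
    out[1] = _laplacian(B, params.D_b, grid) - bind + dis
    out[2] = (_laplacian(Pf, params.D_free_pal, grid) - bind + dis
              - pg_on + pg_off)
    out[3] = pg_on - pg_off
    bind_v = params.alpha * Bv * Pf
    dis_v = (beta + params.gamma) * Cv
    out[4] = _laplacian(Cv, params.D_c, grid) + bind_v - dis_v
    out[5] = _laplacian(Bv, params.D_b, grid) - bind_v + dis_v
    return out


def frap_solution(
    params: TolPalParams,
    beta: TransportProfile,
    totals: SpeciesTotals,
    protocol: FrapProtocol,
    bleach: BleachFunction,
    steady: TolPalState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> dict:
    """Full coupled trajectory of the FRAP simulation.

    Returns a dict with the steady state, the post-bleach frame times and the
    species trajectories ``total`` (4, n_frames, n) and ``visible``
    (n_visible_species, n_frames, n).
    """
    grid = beta.grid
    if bleach.factor.size != grid.n:
        raise ValidationError("bleach function and transport grid mismatch")
    if steady is None:
        steady = tolpal_steady_state(params, beta, totals)
    f = bleach.factor
    if protocol.labelled == "pal":
        nsp, rhs = 7, _frap_rhs_pal
        visible0 = [steady.C * f, steady.P_f * f, steady.P_b * f]
    else:
        nsp, rhs = 6, _frap_rhs_tolb
        visible0 = [steady.C * f, steady.B * f]
    arr0 = np.vstack([steady.as_array()] + [np.asarray(v) for v in visible0])

    def rhs_flat(t, y):
        return _pack(rhs(_unpack(y, nsp), params, beta.beta, grid))

    t_post = protocol.dt * np.arange(protocol.n_postbleach)
    sol = _integrate_banded(rhs_flat, _pack(arr0), (0.0, float(t_post[-1])),
                            nsp, t_eval=t_post, rtol=rtol,
                            atol=atol * totals.pal_total * 1e-3)
    if not sol.success:
        raise IntegrationError(f"FRAP integration failed: {sol.message}",
                               last_time=float(sol.t[-1]) if sol.t.size else 0.0)
    frames = np.stack([_unpack(sol.y[:, k], nsp) for k in range(sol.t.size)],
                      axis=1)  # (nsp, n_frames, n)
    return {
        "steady": steady,
        "t_post": t_post,
        "total": frames[:4],
        "visible": frames[4:],
    }


def simulate_frap(
    params: TolPalParams,
    beta: TransportProfile,
    totals: SpeciesTotals,
    protocol: FrapProtocol,
    bleach: BleachFunction,
    steady: TolPalState | None = None,
    rtol: float = 1e-8,
) -> Kymograph:
    """Simulated FRAP kymograph of the labelled species' visible signal.

    Pre-bleach rows are the labelled species' steady-state profile; post-bleach
    rows sum the visible sub-populations (Pal: C_v + P_fv + P_bv;
    TolB: C_v + B_v).
    """
    sol = frap_solution(params, beta, totals, protocol, bleach, steady=steady,
                        rtol=rtol)
    steady_state = sol["steady"]
    if protocol.labelled == "pal":
        pre = steady_state.total_pal_profile()
    else:
        pre = steady_state.total_tolB_profile()
    post = sol["visible"].sum(axis=0)  # (n_frames, n)
    values = np.vstack([np.tile(pre, (protocol.n_prebleach, 1)), post])
    values = np.clip(values, 0.0, None)
    return Kymograph(times=protocol.frame_times(), positions=beta.grid.x,
                     values=values, n_prebleach=protocol.n_prebleach,
                     pixel_size=beta.grid.dx, labelled=protocol.labelled)


# ---------------------------------------------------------------------------
# Toy-model FRAP (both compartments labelled)
# ---------------------------------------------------------------------------

def _toy_frap_rhs(arr, params, beta, grid):
    """(4, n) rhs: totals (B_out, B_in) + visible (B_out_v, B_in_v)."""
    out = np.empty_like(arr)
    for k in (0, 2):
        exch = params.alpha * arr[k + 1] - beta * arr[k]
        out[k] = _laplacian(arr[k], params.D_out, grid) + exch
        out[k + 1] = _laplacian(arr[k + 1], params.D_in, grid) - exch
    return out


def toy_simulate_frap(
    params: ToyParams,
    beta: TransportProfile,
    protocol: FrapProtocol,
    bleach: BleachFunction,
    steady: ToyProfiles | None = None,
    rtol: float = 1e-8,
) -> Kymograph:
    """Simulated FRAP on the two-compartment model; signal = B_out_v + B_in_v."""
    grid = beta.grid
    if steady is None:
        steady = toy_steady_state(params, n=grid.n)
    f = bleach.factor
    arr0 = np.vstack([steady.B_out, steady.B_in,
                      steady.B_out * f, steady.B_in * f])

    def rhs_flat(t, y):
        return _pack(_toy_frap_rhs(_unpack(y, 4), params, beta.beta, grid))

    t_post = protocol.dt * np.arange(protocol.n_postbleach)
    sol = _integrate_banded(rhs_flat, _pack(arr0), (0.0, float(t_post[-1])), 4,
                            t_eval=t_post, rtol=rtol, atol=1e-12)
    if not sol.success:
        raise IntegrationError(f"toy FRAP integration failed: {sol.message}",
                               last_time=float(sol.t[-1]) if sol.t.size else 0.0)
    frames = np.stack([_unpack(sol.y[:, k], 4) for k in range(sol.t.size)],
                      axis=1)
    pre = steady.B_out + steady.B_in
    post = frames[2] + frames[3]
    values = np.vstack([np.tile(pre, (protocol.n_prebleach, 1)), post])
    return Kymograph(times=protocol.frame_times(), positions=grid.x,
                     values=np.clip(values, 0.0, None),
                     n_prebleach=protocol.n_prebleach, pixel_size=grid.dx,
                     labelled="toy")
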