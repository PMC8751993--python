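"""SpatialFRAP: inference of a spatially varying effective diffusion
coefficient from a FRAP kymograph.

The observed fluorescence profile is modelled with the Fokker-Planck equation

    dc/dt = d^2/dx^2 ( D_eff(x) c ),

whose steady state under reflective boundaries is proportional to
``1/D_eff(x)``.  The pre-bleach (equilibrium) profile therefore fixes the
*shape* of ``D_eff(x)`` up to a constant; the constant is found by solving the
equation forward from the first post-bleach frame and fitting the predicted
recovery to the remaining post-bleach frames with a derivative-free search.

Because the equation is linear and ``D_eff = scale * shape``, the solution at
any candidate scale is obtained from a single symmetric eigendecomposition of
the discrete operator (the scale only multiplies the eigenvalues), which makes
the scale fit essentially free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import FitError, ValidationError
from .kymo import Kymograph
from .optimize import pattern_search

__all__ = [
    "DeffProfile",
    "preprocess_kymograph",
    "deff_shape_from_prebleach",
    "fokker_planck_solve",
    "fit_deff_scale",
    "spatialfrap",
]

COST_WEIGHT = 1e5          # mean-square errors are rescaled to avoid tiny numbers
SCALE_INIT = 1e-3          # um^2/s, initial guess for the diffusion constant
SCALE_BOUNDS = (1e-6, 1.0)  # um^2/s


@dataclass
class DeffProfile:
    """Spatially varying effective diffusion coefficient along the cell axis."""

    positions: np.ndarray          # relative long-axis coordinates
    D_eff: np.ndarray              # um^2/s, one value per retained pixel
    scale: float                   # fitted mean D_eff (um^2/s)
    fit_cost: float                # weighted mean-square error of the fit
    degenerate: bool = False       # cost was insensitive to the scale

    @property
    def mean(self) -> float:
        return float(np.mean(self.D_eff))


def preprocess_kymograph(kymo: Kymograph, trim: int = 2) -> Kymograph:
    """Trim ``trim`` pixels from each end and normalise each frame to sum 1.

    The trimmed pixels remove the unreliable low signal at the cell poles.
    """
    if kymo.n_frames < 3:
        raise ValidationError("need at least 3 frames for SpatialFRAP")
    if kymo.width < 2 * trim + 4:
        raise ValidationError(
            f"kymograph width {kymo.width} too narrow to trim {trim} pixels "
            "from each end")
    sl = slice(trim, kymo.width - trim) if trim else slice(None)
    vals = kymo.values[:, sl]
    sums = vals.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValidationError("a frame has non-positive total signal")
    return Kymograph(times=kymo.times, positions=kymo.positions[sl],
                     values=vals / sums, n_prebleach=kymo.n_prebleach,
                     pixel_size=kymo.pixel_size, labelled=kymo.labelled)


def deff_shape_from_prebleach(prebleach: np.ndarray,
                              smooth_window: int | None = None) -> np.ndarray:
    """Unnormalised D_eff shape: the reciprocal of the equilibrium profile.

    ``smooth_window`` applies a centred moving average to the pre-bleach
    profile before taking the reciprocal, damping noise amplification; leave
    unset for noiseless data.
    """
    prof = np.asarray(prebleach, dtype=float)
    if smooth_window and smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(prof, pad, mode="edge")
        prof = np.convolve(padded, kern, mode="valid")[: prof.size]
    if np.any(prof <= 0):
        raise ValidationError(
            "pre-bleach profile must be strictly positive; trim the poles")
    return 1.0 / prof


class _FokkerPlanckPropagator:
    """exp(t * A) for A c = d^2(shape * c)/dx^2 via symmetric eigenbasis.

    With D_eff = scale * shape, the solution at scale ``s`` and time ``t``
    equals the unit-scale solution at time ``s * t``.
    """

    def __init__(self, shape: np.ndarray, dx: float):
        shape = np.asarray(shape, dtype=float)
        if np.any(shape <= 0):
            raise ValidationError("D_eff shape must be strictly positive")
        n = shape.size
        # Second-difference matrix with zero-flux (Neumann) closure; columns
        # sum to zero so the plain frame sum is conserved.
        M = (np.diag(np.full(n - 1, 1.0), 1) + np.diag(np.full(n - 1, 1.0), -1)
             - 2.0 * np.eye(n))
        M[0, 0] = M[-1, -1] = -1.0
        M /= dx**2
        r = np.sqrt(shape)
        # A = M diag(shape) is similar to the symmetric diag(r) M diag(r).
        A_sym = (M * r[None, :]) * r[:, None]
        lam, Q = linalg.eigh(A_sym)
        self._r = r
        self._lam = lam
        self._Q = Q

    def propagate(self, c0: np.ndarray, times: np.ndarray,
                  scale: float = 1.0) -> np.ndarray:
        """Solution frames at the given times (rows) from initial profile c0."""
        # A = M diag(shape) = R^-1 (R M R) R with R = diag(sqrt(shape)), so
        # exp(At) c0 = R^-1 Q exp(lam t) Q^T R c0.
        z0 = self._Q.T @ (self._r * c0)
        texp = np.exp(np.outer(np.asarray(times, float) * scale, self._lam))
        return (texp * z0[None, :]) @ self._Q.T / self._r[None, :]


def fokker_planck_solve(Deff: np.ndarray, c0: np.ndarray, times: np.ndarray,
                        dx: float = 1.0) -> np.ndarray:
    """Frames of the Fokker-Planck equation with diffusivity field ``Deff``."""
    Deff = np.asarray(Deff, float)
    c0 = np.asarray(c0, float)
    if Deff.size != c0.size:
        raise ValidationError("Deff and initial profile differ in length")
    return _FokkerPlanckPropagator(Deff, dx).propagate(c0, times, scale=1.0)


def fit_deff_scale(kymo: Kymograph, shape: np.ndarray,
                   init: float = SCALE_INIT,
                   bounds: tuple[float, float] = SCALE_BOUNDS,
                   rel_positions: np.ndarray | None = None) -> DeffProfile:
    """Fit the proportionality constant of ``D_eff = scale * shape``.

    ``kymo`` must already be preprocessed (trimmed, frame-normalised).  The
    first post-bleach frame is the initial condition; the predicted recovery
    is compared with all post-bleach frames by weighted mean-square error and
    the scale minimised by pattern search from the stated initial guess.
    The returned ``scale`` is the spatial mean of ``D_eff`` in um^2/s.
    """
    post = kymo.postbleach()
    if post.shape[0] < 2:
        raise ValidationError("need at least 2 post-bleach frames")
    shape = np.asarray(shape, float)
    shape_n = shape / shape.mean()
    prop = _FokkerPlanckPropagator(shape_n, kymo.pixel_size)
    t_post = kymo.times[kymo.n_prebleach:]
    t_rel = t_post - t_post[0]
    c0 = post[0]

    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def cost_of_log(u):
        u = float(u[0])
        if u < lo or u > hi:
            return np.inf
        pred = prop.propagate(c0, t_rel, scale=np.exp(u))
        return COST_WEIGHT * float(np.mean((pred - post) ** 2))

    res = pattern_search(cost_of_log, [np.log(init)], step0=np.log(10.0) / 2,
                         tol=1e-5, max_evals=120)
    if not np.isfinite(res.fun):
        raise FitError("non-finite SpatialFRAP cost")
    scale = float(np.exp(res.x[0]))
    # Degeneracy check: without bleach contrast (first post-bleach frame
    # already at the equilibrium profile) the cost cannot constrain the scale.
    equil = (1.0 / shape_n)
    equil /= equil.sum() / c0.sum()
    contrast = np.sqrt(np.mean((c0 - equil) ** 2)) / np.mean(np.abs(c0))
    degenerate = bool(contrast < 1e-6)
    rel = kymo.rel_positions if rel_positions is None else rel_positions
    return DeffProfile(positions=rel, D_eff=scale * shape_n, scale=scale,
                       fit_cost=float(res.fun), degenerate=degenerate)


def spatialfrap(kymo: Kymograph, trim: int = 2,
                smooth_window: int | None = None) -> DeffProfile:
    """Full SpatialFRAP pipeline: preprocess, shape from pre-bleach, scale fit.

    Positions of the returned profile are on the relative long axis [0, 1] of
    the untrimmed cell, so the septum of a centrally bleached cell sits at 0.5.
    """
    if kymo.n_prebleach < 1:
        raise ValidationError("SpatialFRAP needs at least one pre-bleach frame")
    proc = preprocess_kymograph(kymo, trim=trim)
    shape = deff_shape_from_prebleach(proc.prebleach_profile(),
                                      smooth_window=smooth_window)
    lo, hi = kymo.positions[0], kymo.positions[-1]
    rel = (proc.positions - lo) / (hi - lo)
    return fit_deff_scale(proc, shape, rel_positions=rel)
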