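"""Synthetic per-cell FRAP datasets.

Emulates the structure of the experimental data the analysis assumes:
per-cell fluorescence line profiles acquired before and after a central
bleach, with cell-to-cell length variability, pixelation at the microscope's
sampling, and multiplicative measurement noise; per-condition datasets of
~30 cells are averaged on a common relative-position grid exactly as the
experimental kymographs were.

The generator's defaults encode the study conditions: dividing cells average
4.0 um and use septally localised transport, non-dividing cells average
2.8 um with homogeneous transport; Pal imaging is 1 pre-bleach + 20
post-bleach frames at 30 s, TolB imaging 2 + 75 frames at 2 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ValidationError
from .frap import FrapProtocol, simulate_frap, synthetic_bleach_function
from .kymo import Kymograph, resample_frames
from .model import SpeciesTotals, TolPalParams, make_grid

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_cell",
    "average_kymographs",
    "generate_dataset",
]

NOISE_MODELS = ("none", "multiplicative_gaussian", "poisson")


@dataclass(frozen=True)
class SyntheticConfig:
    ground_truth: TolPalParams = field(default_factory=TolPalParams)
    totals: SpeciesTotals = field(default_factory=SpeciesTotals)
    n_cells: int = 30
    cell_type: str = "dividing"          # or "nondividing"
    length_mean: float | None = None     # default 4.0 / 2.8 um by cell type
    length_cv: float = 0.1
    pixel_size: float = 0.05             # um
    noise_model: str = "multiplicative_gaussian"
    noise_cv: float = 0.02
    poisson_scale: float = 1e3           # expected counts at unit concentration
    protocol: FrapProtocol = field(default_factory=FrapProtocol.pal_default)
    bleach_edge_sigma: float = 0.05      # um, finite bleach-spot edge
    edge_attenuation: float = 0.0        # optional polar signal loss (0..1)
    n_grid: int = 81                     # simulation nodes per cell
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.cell_type not in ("dividing", "nondividing"):
            raise ValidationError(f"unknown cell type {self.cell_type!r}")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"unknown noise model {self.noise_model!r}")

    @property
    def mean_length(self) -> float:
        if self.length_mean is not None:
            return self.length_mean
        return 4.0 if self.cell_type == "dividing" else 2.8

    @property
    def transport_mode(self) -> str:
        return ("truncated_normal" if self.cell_type == "dividing"
                else "homogeneous")


@dataclass
class SyntheticDataset:
    cells: list
    average: Kymograph
    config: SyntheticConfig
    seed: int

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "cells").mkdir(parents=True, exist_ok=True)
        for i, cell in enumerate(self.cells):
            cell.save(outdir / "cells" / f"cell_{i:03d}.tsv")
        self.average.save(outdir / "average.tsv")
        manifest = {
            "seed": self.seed,
            "n_cells": len(self.cells),
            "cell_type": self.config.cell_type,
            "mean_length": self.config.mean_length,
            "length_cv": self.config.length_cv,
            "pixel_size": self.config.pixel_size,
            "noise_model": self.config.noise_model,
            "noise_cv": self.config.noise_cv,
            "labelled": self.config.protocol.labelled,
            "ground_truth": self.config.ground_truth.to_dict(),
            "totals": {"tolB_total": self.config.totals.tolB_total,
                       "pal_total": self.config.totals.pal_total},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _draw_length(config: SyntheticConfig, rng: np.random.Generator) -> float:
    if config.length_cv == 0:
        return config.mean_length
    sd = config.length_cv * config.mean_length
    # truncate at +/- 3 coefficient-of-variation to exclude unphysical lengths
    u = rng.random()
    return float(stats.truncnorm.ppf(u, -3.0, 3.0, loc=config.mean_length,
                                     scale=sd))


def generate_cell(config: SyntheticConfig, cell_index: int) -> Kymograph:
    """One cell's kymograph: simulate, pixelate, attenuate poles, add noise.

    Deterministic given (config.seed, cell_index).
    """
    rng = np.random.default_rng([config.seed, cell_index])
    L = _draw_length(config, rng)
    grid = make_grid(L, config.n_grid)
    beta = config.ground_truth.transport_profile(grid, config.transport_mode)
    bleach = synthetic_bleach_function(config.protocol, grid,
                                       edge_sigma=config.bleach_edge_sigma)
    kymo = simulate_frap(config.ground_truth, beta, config.totals,
                         config.protocol, bleach)
    # pixelate: sample at the microscope's pixel centres
    n_px = max(int(np.floor(L / config.pixel_size)) + 1, 8)
    px = np.linspace(-L / 2, L / 2, n_px)
    vals = resample_frames(kymo.values, kymo.rel_positions,
                           (px - px[0]) / (px[-1] - px[0]))
    if config.edge_attenuation > 0:
        att = np.ones(n_px)
        ramp = np.linspace(1.0 - config.edge_attenuation, 1.0, 3)
        att[:3] = ramp
        att[-3:] = ramp[::-1]
        vals = vals * att[None, :]
    if config.noise_model == "multiplicative_gaussian" and config.noise_cv > 0:
        eps = rng.normal(0.0, config.noise_cv, size=vals.shape)
        vals = vals * (1.0 + np.clip(eps, -0.99, None))
    elif config.noise_model == "poisson":
        lam = np.clip(vals * config.poisson_scale, 0.0, None)
        vals = rng.poisson(lam).astype(float) / config.poisson_scale
    return Kymograph(times=kymo.times, positions=px,
                     values=np.clip(vals, 0.0, None),
                     n_prebleach=config.protocol.n_prebleach,
                     pixel_size=config.pixel_size,
                     labelled=config.protocol.labelled)


def average_kymographs(cells: list, n_points: int = 64,
                       mean_length: float | None = None) -> Kymograph:
    """Frame-wise average on a common relative-position grid.

    Each cell's frames are linearly interpolated onto ``n_points`` relative
    positions in [0, 1] and averaged; positions of the result are mapped back
    to um using the mean cell length.
    """
    if not cells:
        raise ValidationError("need at least one cell to average")
    t0 = cells[0].times
    for c in cells[1:]:
        if c.times.size != t0.size or not np.allclose(c.times, t0):
            raise ValidationError("cells have mismatched frame times")
    rel = np.linspace(0.0, 1.0, n_points)
    stack = np.stack([resample_frames(c.values, c.rel_positions, rel)
                      for c in cells])
    avg = stack.mean(axis=0)
    if mean_length is None:
        mean_length = float(np.mean([c.positions[-1] - c.positions[0]
                                     for c in cells]))
    positions = (rel - 0.5) * mean_length
    return Kymograph(times=t0, positions=positions, values=avg,
                     n_prebleach=cells[0].n_prebleach,
                     pixel_size=mean_length / (n_points - 1),
                     labelled=cells[0].labelled)


def generate_dataset(config: SyntheticConfig, outdir=None,
                     n_average_points: int = 64) -> SyntheticDataset:
    """Generate all cells plus their average; optionally write to ``outdir``."""
    cells = [generate_cell(config, i) for i in range(config.n_cells)]
    average = average_kymographs(cells, n_points=n_average_points,
                                 mean_length=config.mean_length)
    ds = SyntheticDataset(cells=cells, average=average, config=config,
                          seed=config.seed)
    if outdir is not None:
        ds.save(outdir)
    return ds
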