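"""Kymograph container and delimited-text round-tripping.

A kymograph is a frames x positions matrix of fluorescence (or concentration)
line profiles along the cell's long axis.  The text format is TSV: '#'-prefixed
header lines carry metadata, the first data row holds the position coordinates
(with a leading 'time' placeholder cell), and each subsequent row is one frame
with a leading time column.  Values are written with 9 significant digits and
round-trip bit-exactly at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

__all__ = ["Kymograph", "resample_frames"]


@dataclass
class Kymograph:
    times: np.ndarray                 # frame times (s), strictly increasing
    positions: np.ndarray             # axis coordinates (um)
    values: np.ndarray                # (n_frames, n_positions)
    n_prebleach: int = 1
    pixel_size: float | None = None   # um per column
    labelled: str = "pal"             # labelled species

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.positions.size):
            raise ValidationError(
                f"kymograph shape {self.values.shape} does not match "
                f"{self.times.size} times x {self.positions.size} positions")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if self.pixel_size is None and self.positions.size > 1:
            self.pixel_size = float(np.mean(np.diff(self.positions)))

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def width(self) -> int:
        return self.positions.size

    @property
    def rel_positions(self) -> np.ndarray:
        """Positions mapped to the relative long-axis coordinate [0, 1]."""
        lo, hi = self.positions[0], self.positions[-1]
        return (self.positions - lo) / (hi - lo)

    def prebleach_profile(self) -> np.ndarray:
        """Average of the pre-bleach frames."""
        if self.n_prebleach < 1:
            raise ValidationError("kymograph has no pre-bleach frames")
        return self.values[: self.n_prebleach].mean(axis=0)

    def postbleach(self) -> np.ndarray:
        return self.values[self.n_prebleach:]

    def resampled(self, new_rel_positions: np.ndarray) -> "Kymograph":
        """Linear interpolation of every frame onto a new relative-position grid."""
        new_rel = np.asarray(new_rel_positions, dtype=float)
        vals = resample_frames(self.values, self.rel_positions, new_rel)
        span = self.positions[-1] - self.positions[0]
        new_pos = self.positions[0] + new_rel * span
        return replace(self, positions=new_pos, values=vals,
                       pixel_size=float(span * np.mean(np.diff(new_rel)))
                       if new_rel.size > 1 else self.pixel_size)

    # -- text IO ------------------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_prebleach\t{self.n_prebleach}\n")
            fh.write(f"# pixel_size\t{self.pixel_size!r}\n")
            fh.write(f"# labelled\t{self.labelled}\n")
            fh.write("time\t" + "\t".join(f"{p:.9g}" for p in self.positions)
                     + "\n")
            for t, row in zip(self.times, self.values):
                fh.write(f"{t:.9g}\t" + "\t".join(f"{v:.9g}" for v in row)
                         + "\n")

    @classmethod
    def load(cls, path) -> "Kymograph":
        meta = {}
        rows = []
        positions = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("\t")
                    meta[key.strip()] = val.strip()
                    continue
                cells = line.split("\t")
                if positions is None:
                    positions = np.array([float(c) for c in cells[1:]])
                    continue
                rows.append([float(c) for c in cells])
        if positions is None or not rows:
            raise ValidationError(f"no kymograph data found in {path}")
        arr = np.array(rows)
        pixel = meta.get("pixel_size", "None")
        return cls(
            times=arr[:, 0], positions=positions, values=arr[:, 1:],
            n_prebleach=int(meta.get("n_prebleach", 1)),
            pixel_size=None if pixel == "None" else float(pixel),
            labelled=meta.get("labelled", "pal"),
        )


def resample_frames(values: np.ndarray, rel_from: np.ndarray,
                    rel_to: np.ndarray) -> np.ndarray:
    """Row-wise linear interpolation between relative-position grids."""
    out = np.empty((values.shape[0], rel_to.size))
    for i, row in enumerate(values):
        out[i] = np.interp(rel_to, rel_from, row)
    return out
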