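#!/usr/bin/env python
"""Validation of the SpatialFRAP inversion on known diffusivity fields.

Forward-simulates Fokker-Planck kymographs with known constant and spatially
varying effective diffusion coefficients, then inverts them with the full
SpatialFRAP pipeline (pole trimming, frame normalisation, shape from the
pre-bleach profile, derivative-free scale fit).  Finding: noiseless inputs
are recovered to well under 1%, and 2% multiplicative pixel noise degrades
the recovery to only a few percent once the pre-bleach profile is smoothed
with a 3-pixel moving average.

Writes results/spatialfrap_validation.json.
"""

import json
from pathlib import Path

from tolpal import workflows

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    res = workflows.spatialfrap_selfinversion(seed=1)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "spatialfrap_validation.json", "w") as fh:
        json.dump(res, fh, indent=2)
    print(f"constant-D sup-norm relative error:  {res['constant_sup_err']:.2e}")
    print(f"varying-D sup-norm relative error:   {res['varying_sup_err']:.2e}")
    print(f"2%-noise median mean relative error: "
          f"{res['noisy_median_err']:.3f} over 5 noise realisations")


if __name__ == "__main__":
    main()
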