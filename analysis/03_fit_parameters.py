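#!/usr/bin/env python
"""Recover the free model parameters from synthetic FRAP data.

Generates noiseless average Pal kymographs for dividing (L = 4.0 um, septal
transport) and non-dividing (L = 2.8 um, uniform transport) cells at the
reference parameters, then fits (D_c, D_b, beta0) — via a = D_c - D_b and
b = D_c/D_b — starting from a deliberately wrong initial point (a x2,
b-1 x1.5, beta0 x0.5).  Finding: the fit recovers the complex and free-TolB
diffusion coefficients to within a few percent and the transport strength to
within ~10%, demonstrating that the experimental design identifies all three
parameters.

Writes results/fit_recovery.json.  Takes a couple of minutes.
"""

import json
from pathlib import Path

from tolpal import workflows

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    rec = workflows.parameter_recovery(seed=1)
    OUT.mkdir(exist_ok=True)
    payload = {k: v for k, v in rec.items() if k != "fit"}
    payload["n_evals"] = rec["fit"].n_evals
    payload["cost"] = rec["fit"].cost
    with open(OUT / "fit_recovery.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"D_c   = {rec['D_c']:.4g} um^2/s  "
          f"(truth 0.0068, error {rec['D_c_rel_err']:.1%})")
    print(f"D_b   = {rec['D_b']:.4g} um^2/s  "
          f"(truth 0.0036, error {rec['D_b_rel_err']:.1%})")
    print(f"beta0 = {rec['beta0']:.4g} um/s   "
          f"(truth 17, error {rec['beta0_rel_err']:.1%})")
    print(f"cost {rec['fit'].cost:.3e} after {rec['fit'].n_evals} evaluations")


if __name__ == "__main__":
    main()
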