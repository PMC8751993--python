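#!/usr/bin/env python
"""Does exchange between mobility states speed up FRAP recovery?

Simulates bleaching of the two-compartment model twice from the *same*
steady state: once with inner/outer exchange active (a = 50, b = 1,
d = 0.02) and once with all exchange switched off.  The average diffusion
coefficient of the population is identical in both runs; only the reshuffling
between fast and slow states differs.  Finding: the bleached region reaches
90% of its recovered asymptote several-fold sooner with exchange — mobility
measured by FRAP reflects turnover, not just diffusion coefficients.

Writes results/exchange_recovery.json.
"""

import json
from pathlib import Path

from tolpal import workflows

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    res = workflows.exchange_recovery_speed()
    OUT.mkdir(exist_ok=True)
    with open(OUT / "exchange_recovery.json", "w") as fh:
        json.dump(res, fh, indent=2)
    print(f"frames to 90% recovery with exchange:    {res['frames_with']:.0f}")
    print(f"frames to 90% recovery without exchange: "
          f"{res['frames_without']:.0f}")
    print(f"speedup: {res['speedup']:.1f}x")


if __name__ == "__main__":
    main()
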