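#!/usr/bin/env python
"""Behaviour of the through-origin richness-contrast (MacroCAIC) regression.

Two studies on 60-taxon synthetic universes: type-I error when host
diversity has no effect on richness, and power under the default positive
effect. Writes results/caic_behaviour.json.
"""

import argparse
import json
from pathlib import Path

from oscillate.experiments import caic_null_type_i, caic_power


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--null-reps", type=int, default=500)
    ap.add_argument("--power-reps", type=int, default=100)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    null = caic_null_type_i(n_reps=args.null_reps, seed=args.seed)
    power = caic_power(n_reps=args.power_reps, seed=args.seed + 1)
    payload = {
        "null_rejection_rate": null["rejection_rate"],
        "null_reps": null["n_reps"],
        "power": power["power"],
        "power_reps": power["n_reps"],
        "power_slope_mean": power["slope_mean"],
    }
    (args.out_dir / "caic_behaviour.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(
        f"Null rejection at alpha=0.05: {null['rejection_rate']:.3f} over "
        f"{null['n_reps']} replicates (nominal 0.05)."
    )
    print(
        f"Power under the default effect: {power['power']:.2f} over "
        f"{power['n_reps']} replicates (mean through-origin slope "
        f"{power['slope_mean']:.2f}). The log richness-ratio response is "
        f"noisier than the PGLS fit on the same data, so its power is "
        f"substantially lower."
    )


if __name__ == "__main__":
    main()
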