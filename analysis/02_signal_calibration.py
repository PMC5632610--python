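#!/usr/bin/env python
"""Calibrate the permutation test of phylogenetic signal.

Two studies on 100-tip pure-birth trees: type-I error under iid
Bernoulli(1/2) tip states, and power against traits truly evolved at a low
Mk rate (0.1 per unit tree depth). Writes results/signal_calibration.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from oscillate.experiments import signal_power, signal_type_i_error


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--null-reps", type=int, default=500)
    ap.add_argument("--power-reps", type=int, default=200)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    null = signal_type_i_error(n_reps=args.null_reps, n_tips=100,
                               n_perm=99, seed=args.seed)
    power = signal_power(n_reps=args.power_reps, n_tips=100,
                         q_unit_depth=0.1, n_perm=99, seed=args.seed + 1)
    payload = {
        "null_rejection_rate": null["rejection_rate"],
        "null_reps": null["n_reps"],
        "null_p_deciles": np.percentile(
            null["p_values"], np.arange(10, 100, 10)).round(3).tolist(),
        "power_q0.1": power["power"],
        "power_reps": power["n_reps"],
    }
    (args.out_dir / "signal_calibration.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(
        f"Null rejection at alpha=0.05: {null['rejection_rate']:.3f} over "
        f"{null['n_reps']} replicates (nominal 0.05)."
    )
    print(
        f"Power against Mk rate 0.1/depth: {power['power']:.2f} over "
        f"{power['n_reps']} replicates. Weak-signal replicates are those "
        f"whose minority state touches only one or two tips."
    )


if __name__ == "__main__":
    main()
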