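#!/usr/bin/env python
"""Fit the exponential velocity-decay model to the extracted front lines.

Fits Vh(t) = A exp(-k t) + c by nonlinear least squares. The sneeze is
fitted with c pinned to 0 (calm room, no residual drift); the cough with
c pinned to 27 cm/s, the directed air-conditioning current of the
simulated room. Non-positive front-line points (tracking artifacts at
late, slow frames) are left out. Writes results/04_decay_models.json.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from plumekin import fit_decay  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")
RESULTS = os.path.join(ROOT, "results")

GENERATING = {
    "sneeze": {"A": 1500.0, "k": 22.0, "c": 0.0, "fix_offset": 0.0},
    "cough": {"A": 1100.0, "k": 32.0, "c": 27.0, "fix_offset": 27.0},
}


def main() -> None:
    models = {}
    for name, ref in GENERATING.items():
        df = pd.read_csv(os.path.join(RESULTS, f"03_frontline_{name}.csv"))
        df = df[df.vh_cms > 0]
        model = fit_decay(
            (df.t_s.to_numpy(), df.vh_cms.to_numpy()),
            fix_offset=ref["fix_offset"],
        )
        models[name] = model.to_dict() | {
            "generating_A_cms": ref["A"],
            "generating_k_per_s": ref["k"],
            "generating_c_cms": ref["c"],
        }
        print(
            f"{name}: Vh(t) = {model.amplitude:.0f} exp(-{model.rate:.1f} t)"
            f" + {model.offset:.0f}  [generating: {ref['A']:.0f} exp(-{ref['k']:.0f} t)"
            f" + {ref['c']:.0f}]  rms {model.rms:.1f} cm/s on {model.n_points} points,"
            f" k error {100 * abs(model.rate - ref['k']) / ref['k']:.1f}%"
        )
    out = os.path.join(RESULTS, "04_decay_models.json")
    with open(out, "w") as fh:
        json.dump(models, fh, indent=2)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
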