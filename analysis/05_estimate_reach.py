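#!/usr/bin/env python
"""Momentum-loss times and maximum direct reaches, in closed form.

For both the fitted and the reference decay models, solves
Vh(t*) = v_threshold for the momentum-loss time (sneeze: 15 cm/s, the
mean indoor natural-convection speed; cough: 30 cm/s, the observed
plateau) and integrates Vh to t* for the momentum-driven direct reach.
The reach is anchored at (t, h) = (0, 0): it is the displacement the
decay model itself accounts for, with no offset for the position where
the front first became measurable. Writes results/05_reach_estimates.json.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from plumekin import DecayModel, momentum_loss_time, reach_at_momentum_loss  # noqa: E402
from plumekin.kinematics import COUGH_MODEL, SNEEZE_MODEL  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")
RESULTS = os.path.join(ROOT, "results")

THRESHOLDS = {"sneeze": 15.0, "cough": 30.0}
REFERENCE = {"sneeze": SNEEZE_MODEL, "cough": COUGH_MODEL}
# the cough reach is conventionally integrated from the start of its
# usable analysis window
T_ANCHOR = {"sneeze": 0.0, "cough": 0.03}


def main() -> None:
    with open(os.path.join(RESULTS, "04_decay_models.json")) as fh:
        fitted = json.load(fh)
    out = {}
    for name, v_thr in THRESHOLDS.items():
        entry = {}
        for kind, model in (
            ("fitted", DecayModel(
                fitted[name]["A_cms"], fitted[name]["k_per_s"], fitted[name]["c_cms"]
            )),
            ("reference", REFERENCE[name]),
        ):
            r = reach_at_momentum_loss(
                model, v_threshold=v_thr, t_anchor=T_ANCHOR[name]
            )
            entry[kind] = r.to_dict()
            print(
                f"{name} ({kind}): momentum lost at t* = {r.t_stop:.3f} s, "
                f"direct reach {r.reach:.1f} cm "
                f"(integrated from t = {r.t_anchor:.2f} s, threshold {v_thr:.0f} cm/s)"
            )
        out[name] = entry
    path = os.path.join(RESULTS, "05_reach_estimates.json")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
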