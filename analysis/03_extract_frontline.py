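#!/usr/bin/env python
"""Front-line extraction from the tracked vector fields.

Excludes fast-falling large droplets (aerodynamic diameter > 300 um by
their Stokes settling velocity), then reduces each frame's vector field
to the distal-margin point (t, h, Vh). Analysis windows follow the two
events' usable ranges: 0.04-0.20 s for the sneeze (earlier frames are too
dense to resolve individual particles) and 0.03-0.20 s for the cough.
Writes the front-line series and the full distance-time-velocity maps to
results/.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from plumekin import (  # noqa: E402
    exclude_fast_falling,
    export_velocity_map,
    extract_frontline,
    fields_from_dataframe,
)

ROOT = os.path.join(os.path.dirname(__file__), "..")
SCRATCH = os.path.join(ROOT, "scratch")
RESULTS = os.path.join(ROOT, "results")

WINDOWS = {"sneeze": (0.04, 0.20), "cough": (0.03, 0.20)}


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    for name, window in WINDOWS.items():
        cfg = json.load(open(os.path.join(SCRATCH, name, "truth_config.json")))
        df = pd.read_csv(os.path.join(SCRATCH, f"{name}_vectors.csv"))
        fields = fields_from_dataframe(
            df, pixel_size=cfg["pixel_size"], dt=1.0 / cfg["frame_rate"]
        )
        fields = [exclude_fast_falling(f, 300.0) for f in fields]
        mouth_x = cfg["mouth_position"][0]
        series = extract_frontline(fields, mouth_x, window=window, label=name)
        out_csv = os.path.join(RESULTS, f"03_frontline_{name}.csv")
        series.to_dataframe().to_csv(out_csv, index=False, float_format="%.6g")
        with open(os.path.join(RESULTS, f"03_frontline_{name}.json"), "w") as fh:
            json.dump({"event": name, "window_s": list(window),
                       "n_points": len(series)}, fh, indent=2)
        vmap = export_velocity_map(fields, mouth_x)
        vmap.to_csv(
            os.path.join(SCRATCH, f"{name}_velocity_map.csv"), index=False
        )
        n_excl = int(sum(f.excluded.sum() for f in fields))
        print(
            f"{name}: {len(series)} front-line points in {window} s, "
            f"h {series.h.min():.0f} -> {series.h.max():.0f} cm, "
            f"Vh {series.vh.max():.0f} -> {series.vh.min():.0f} cm/s, "
            f"{n_excl} droplet-window exclusions"
        )


if __name__ == "__main__":
    main()
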