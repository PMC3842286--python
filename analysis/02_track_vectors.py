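#!/usr/bin/env python
"""PIV tracking of the simulated recordings.

Loads the frame stacks written by 01_simulate_clouds.py, tracks every
21x21 px interrogation window between consecutive frames (zero-normalized
cross-correlation, subpixel Gaussian peak fit, successive-abandonment
validation), and writes the full vector fields to scratch/ plus a
per-frame tracking summary to results/.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from plumekin import InterrogationGrid, compute_vector_field, load_frames  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")
SCRATCH = os.path.join(ROOT, "scratch")
RESULTS = os.path.join(ROOT, "results")


def main() -> None:
    grid = InterrogationGrid()  # 21x21 px windows, 15 px search radius
    summary = []
    for name in ("sneeze", "cough"):
        cfg = json.load(open(os.path.join(SCRATCH, name, "truth_config.json")))
        seq = load_frames(
            os.path.join(SCRATCH, name, "frames", "*.png"),
            dt=1.0 / cfg["frame_rate"],
            pixel_size=cfg["pixel_size"],
            mouth_position=tuple(cfg["mouth_position"]),
        )
        tables = []
        for i in range(seq.n_frames - 1):
            f = compute_vector_field(seq.frame(i), seq.frame(i + 1), grid)
            df = f.to_dataframe()
            df.insert(0, "frame_index", i)
            tables.append(df)
            summary.append(
                (name, i, f.t, len(f), f.n_valid, int(f.abandonment_counts.sum()))
            )
        all_vectors = pd.concat(tables, ignore_index=True)
        all_vectors.to_csv(
            os.path.join(SCRATCH, f"{name}_vectors.csv"), index=False
        )
        n_valid = int(all_vectors["valid"].sum())
        print(
            f"{name}: {len(tables)} frame pairs, {len(all_vectors)} windows, "
            f"{n_valid} valid vectors "
            f"({100 * n_valid / len(all_vectors):.1f}%)"
        )
    os.makedirs(RESULTS, exist_ok=True)
    out = os.path.join(RESULTS, "02_tracking_summary.csv")
    pd.DataFrame(
        summary,
        columns=["event", "frame_index", "t_s", "n_windows", "n_valid", "abandonments"],
    ).to_csv(out, index=False, float_format="%.6g")
    print(f"wrote vector fields to {SCRATCH}, summary to {out}")


if __name__ == "__main__":
    main()
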