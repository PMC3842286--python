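"""Independent reference implementations used only to check the package.

These are deliberately naive (loops, closed forms, grid search) and share
no code with the implementation under test.
"""

import numpy as np


def zncc_bruteforce(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Spatial-domain zero-normalized cross-correlation, one offset at a time."""
    template = np.asarray(template, dtype=np.float64)
    search = np.asarray(search, dtype=np.float64)
    th, tw = template.shape
    sh, sw = search.shape
    out = np.zeros((sh - th + 1, sw - tw + 1))
    t0 = template - template.mean()
    tn = np.sqrt(np.sum(t0**2))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = search[i : i + th, j : j + tw]
            w0 = win - win.mean()
            wn = np.sqrt(np.sum(w0**2))
            if tn == 0 or wn == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = np.sum(t0 * w0) / (tn * wn)
    return out


def blob_frame(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigma: float = 2.0,
    amplitude: float = 200.0,
) -> np.ndarray:
    """Render Gaussian blobs at continuous (x, y) positions, 8-bit output."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    canvas = np.zeros((h, w), dtype=np.float64)
    for cx, cy in np.atleast_2d(centers):
        canvas += amplitude * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma**2)
        )
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def decay_sse(t: np.ndarray, vh: np.ndarray, a: float, k: float, c: float) -> float:
    return float(np.sum((a * np.exp(-k * t) + c - vh) ** 2))


def grid_search_decay(
    t: np.ndarray,
    vh: np.ndarray,
    a_grid: np.ndarray,
    k_grid: np.ndarray,
    c: float = 0.0,
) -> tuple[float, float, float]:
    """Exhaustive minimizer of the decay-fit objective over a parameter grid."""
    best = (np.inf, np.nan, np.nan)
    for a in a_grid:
        for k in k_grid:
            sse = decay_sse(t, vh, a, k, c)
            if sse < best[0]:
                best = (sse, a, k)
    return best[1], best[2], best[0]
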