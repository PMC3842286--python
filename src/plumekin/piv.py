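"""PIV-style vector analysis of consecutive frames.

Each frame pair is divided into interrogation windows (default 21x21 px,
the reference-area size that makes the spatial resolution about 4.4 cm at
the default calibration). The brightness pattern of each window is located
in the next frame by zero-normalized cross-correlation (ZNCC), the integer
peak is refined to subpixel precision by a per-axis three-point Gaussian
fit, and implausible peaks are discarded by a successive-abandonment pass
that promotes lower-ranked correlation peaks consistent with the
neighborhood median displacement.

Validity gates
--------------
A window yields a valid vector only if (a) its intensity standard
deviation reaches ``min_texture_sd`` (a constant or near-empty window has
no trackable pattern), (b) the best correlation peak reaches ``min_peak``
(independent sensor noise correlates weakly, so this rejects background),
and (c) successive abandonment does not exhaust all candidate peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.feature import match_template, peak_local_max

from .errors import InputError
from .imaging import Frame


@dataclass(frozen=True)
class InterrogationGrid:
    """Geometry and validation thresholds of the interrogation grid."""

    window_size: int = 21  # px, odd
    overlap: int = 0  # px
    search_radius: int = 15  # px, max displacement magnitude per axis
    anchor: tuple[int, int] = (0, 0)  # px offset of the first window
    min_texture_sd: float = 1.0  # 8-bit intensity units
    min_peak: float = 0.3  # ZNCC acceptance threshold
    max_candidates: int = 5
    max_abandonments: int = 5
    abandonment_tol_floor: float = 2.0  # px
    abandonment_mad_factor: float = 3.0

    def __post_init__(self):
        if self.window_size < 5 or self.window_size % 2 == 0:
            raise InputError("window_size must be odd and >= 5")
        if self.search_radius < 1:
            raise InputError("search_radius must be >= 1")
        if not 0 <= self.overlap < self.window_size:
            raise InputError("overlap must satisfy 0 <= overlap < window_size")


@dataclass
class VectorField:
    """Per-window displacement/velocity vectors for one frame pair.

    ``t`` is the midpoint of the two frame timestamps: a displacement over
    [t_a, t_a + dt] measures the mean velocity of that interval, which the
    exponential decay law attains at (approximately) the interval centre.
    """

    centers: np.ndarray  # (n, 2) float px, columns (cx, cy)
    displacements: np.ndarray  # (n, 2) float px, columns (dx, dy)
    velocities: np.ndarray  # (n, 2) float cm/s, columns (vx, vy)
    peaks: np.ndarray  # (n,) float, ZNCC peak value
    valid: np.ndarray  # (n,) bool
    abandonment_counts: np.ndarray  # (n,) int
    excluded: np.ndarray  # (n,) bool, set by droplet filtering
    t: float  # s, midpoint time of the frame pair
    dt: float  # s
    pixel_size: float  # cm/px
    grid_shape: tuple[int, int] = (0, 0)  # (rows, cols)
    reduced_precision: np.ndarray | None = None  # (n,) bool, border peaks

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": np.full(len(self), self.t),
                "cx_px": self.centers[:, 0],
                "cy_px": self.centers[:, 1],
                "dx_px": self.displacements[:, 0],
                "dy_px": self.displacements[:, 1],
                "vx_cms": self.velocities[:, 0],
                "vy_cms": self.velocities[:, 1],
                "peak": self.peaks,
                "valid": self.valid,
                "excluded": self.excluded,
                "abandonment_count": self.abandonment_counts,
            }
        )


def fields_from_dataframe(
    df: pd.DataFrame, pixel_size: float, dt: float
) -> list["VectorField"]:
    """Rebuild per-frame :class:`VectorField`s from a serialized table.

    Inverse of concatenating ``to_dataframe()`` outputs with a
    ``frame_index`` column, as written by the tracking stage.
    """
    fields = []
    for _, g in df.groupby("frame_index", sort=True):
        n = len(g)
        disp = g[["dx_px", "dy_px"]].to_numpy(dtype=float)
        fields.append(
            VectorField(
                centers=g[["cx_px", "cy_px"]].to_numpy(dtype=float),
                displacements=disp,
                velocities=g[["vx_cms", "vy_cms"]].to_numpy(dtype=float),
                peaks=g["peak"].to_numpy(dtype=float),
                valid=g["valid"].to_numpy(dtype=bool),
                abandonment_counts=g["abandonment_count"].to_numpy(dtype=int),
                excluded=g["excluded"].to_numpy(dtype=bool),
                t=float(g["t_s"].iloc[0]),
                dt=dt,
                pixel_size=pixel_size,
            )
        )
    return fields


def correlate(template: np.ndarray, search: np.ndarray) -> np.ndarray | None:
    """ZNCC surface of ``template`` against every placement inside ``search``.

    Returns an array of shape ``(Hs - Ht + 1, Ws - Wt + 1)`` with values in
    [-1, 1]; entry (i, j) is the zero-normalized correlation coefficient of
    the template with the same-size subwindow whose top-left corner is
    (i, j). Returns ``None`` for a constant (zero-variance) template, which
    carries no trackable signal.
    """
    template = np.asarray(template, dtype=np.float64)
    search = np.asarray(search, dtype=np.float64)
    if template.shape[0] > search.shape[0] or template.shape[1] > search.shape[1]:
        raise InputError("template must fit inside the search region")
    if float(template.std()) == 0.0:
        return None
    surf = match_template(search, template, pad_input=False)
    surf = np.nan_to_num(surf, nan=0.0, posinf=0.0, neginf=0.0)
    return np.clip(surf, -1.0, 1.0)


def _gaussian_offset(left: float, center: float, right: float) -> float:
    # Three-point Gaussian fit along one axis. Values are min-shifted to
    # positive before the log transform when necessary.
    vals = np.array([left, center, right], dtype=np.float64)
    lo = vals.min()
    if lo <= 0.0:
        vals = vals - lo + 1e-6
    ln = np.log(vals)
    denom = 2.0 * ln[0] - 4.0 * ln[1] + 2.0 * ln[2]
    if denom == 0.0 or not np.isfinite(denom):
        return 0.0
    delta = (ln[0] - ln[2]) / denom
    if not np.isfinite(delta) or abs(delta) >= 1.0:
        return 0.0
    return float(delta)


def subpixel_peak(
    surface: np.ndarray, peak: tuple[int, int]
) -> tuple[float, float, bool]:
    """Refine an integer correlation peak to subpixel precision.

    Returns ``(row, col, reduced_precision)`` where row/col carry a
    per-axis three-point Gaussian-fit correction in (-1, 1). A peak on the
    surface border cannot be refined; its integer location is returned with
    the ``reduced_precision`` flag set.
    """
    r, c = int(peak[0]), int(peak[1])
    h, w = surface.shape
    if r <= 0 or r >= h - 1 or c <= 0 or c >= w - 1:
        return float(r), float(c), True
    dr = _gaussian_offset(surface[r - 1, c], surface[r, c], surface[r + 1, c])
    dc = _gaussian_offset(surface[r, c - 1], surface[r, c], surface[r, c + 1])
    return r + dr, c + dc, False


def successive_abandonment(
    candidates: Sequence[tuple[float, float]],
    neighbor_displacements: np.ndarray,
    tol_floor: float = 2.0,
    mad_factor: float = 3.0,
    max_iter: int = 5,
    min_neighbors: int = 3,
) -> tuple[int | None, int]:
    """Select the first candidate displacement consistent with the neighborhood.

    ``candidates`` are integer-peak displacements ranked by correlation
    value. The current candidate is abandoned when its distance from the
    neighborhood median displacement exceeds
    ``max(tol_floor, mad_factor * MAD)``, where MAD is the median absolute
    deviation of the neighbors from their median; the next-ranked peak is
    then promoted. Returns ``(chosen_index, abandonment_count)``;
    ``chosen_index`` is None when every candidate was abandoned. With fewer
    than ``min_neighbors`` neighbors there is no meaningful consensus and
    the top candidate is accepted unchanged.
    """
    if len(candidates) == 0:
        return None, 0
    neighbors = np.asarray(neighbor_displacements, dtype=np.float64).reshape(-1, 2)
    if len(neighbors) < min_neighbors:
        return 0, 0
    med = np.median(neighbors, axis=0)
    mad = float(np.median(np.linalg.norm(neighbors - med, axis=1)))
    tol = max(tol_floor, mad_factor * mad)
    n_try = min(len(candidates), max_iter)
    for i in range(n_try):
        cand = np.asarray(candidates[i], dtype=np.float64)
        if np.linalg.norm(cand - med) <= tol:
            return i, i
    return None, n_try


def _grid_centers(
    shape: tuple[int, int], grid: InterrogationGrid
) -> tuple[np.ndarray, np.ndarray]:
    # windows are placed so the full search margin fits inside the frame;
    # otherwise a clamped search region puts small displacements on the
    # correlation-surface border where subpixel refinement is impossible
    h, w = shape
    half = grid.window_size // 2
    margin = half + grid.search_radius
    step = grid.window_size - grid.overlap
    ax, ay = grid.anchor
    cxs = np.arange(ax + margin, w - margin, step)
    cys = np.arange(ay + margin, h - margin, step)
    return cxs, cys


def compute_vector_field(
    frame_a: Frame,
    frame_b: Frame,
    grid: InterrogationGrid | None = None,
    dt: float | None = None,
) -> VectorField:
    """Track every interrogation window from ``frame_a`` into ``frame_b``.

    Runs two passes: a first pass collects ranked candidate peaks per
    window, a second pass validates each window's candidates against the
    median displacement of its (up to 8) grid neighbors and refines the
    accepted peak to subpixel precision. Velocities are
    ``displacement * pixel_size / dt``.
    """
    grid = grid or InterrogationGrid()
    if frame_a.shape != frame_b.shape:
        raise InputError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    if dt is None:
        dt = frame_b.timestamp - frame_a.timestamp
    if dt <= 0:
        raise InputError("dt must be positive")
    a = frame_a.data.astype(np.float64)
    b = frame_b.data.astype(np.float64)
    h, w = a.shape
    half = grid.window_size // 2
    R = grid.search_radius
    cxs, cys = _grid_centers(a.shape, grid)
    rows, cols = len(cys), len(cxs)
    n = rows * cols

    centers = np.zeros((n, 2))
    cand_disps: list[list[tuple[float, float]]] = [[] for _ in range(n)]
    cand_peaks: list[np.ndarray] = [np.empty(0)] * n
    surfaces: list[np.ndarray | None] = [None] * n
    origins = np.zeros((n, 2), dtype=int)  # search-region top-left (x0, y0)
    texture_ok = np.zeros(n, dtype=bool)

    idx = 0
    for cy in cys:
        for cx in cxs:
            centers[idx] = (cx, cy)
            tpl = a[cy - half : cy + half + 1, cx - half : cx + half + 1]
            if float(tpl.std()) < grid.min_texture_sd:
                idx += 1
                continue
            x0, x1 = max(0, cx - half - R), min(w, cx + half + 1 + R)
            y0, y1 = max(0, cy - half - R), min(h, cy + half + 1 + R)
            surf = correlate(tpl, b[y0:y1, x0:x1])
            if surf is None:
                idx += 1
                continue
            coords = peak_local_max(
                surf,
                min_distance=1,
                threshold_abs=grid.min_peak,
                num_peaks=grid.max_candidates,
                exclude_border=False,
            )
            if len(coords) == 0:
                idx += 1
                continue
            vals = surf[coords[:, 0], coords[:, 1]]
            order = np.argsort(-vals)
            coords, vals = coords[order], vals[order]
            texture_ok[idx] = True
            surfaces[idx] = surf
            origins[idx] = (x0, y0)
            cand_disps[idx] = [
                (float(x0 + c - (cx - half)), float(y0 + r - (cy - half)))
                for r, c in coords
            ]
            cand_peaks[idx] = vals
            idx += 1

    provisional = np.full((n, 2), np.nan)
    for i in range(n):
        if texture_ok[i]:
            provisional[i] = cand_disps[i][0]

    disps = np.zeros((n, 2))
    peaks = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    counts = np.zeros(n, dtype=int)
    reduced = np.zeros(n, dtype=bool)

    for i in range(n):
        if not texture_ok[i]:
            continue
        r_i, c_i = divmod(i, cols)
        neigh = []
        for drow in (-1, 0, 1):
            for dcol in (-1, 0, 1):
                if drow == 0 and dcol == 0:
                    continue
                rr, cc = r_i + drow, c_i + dcol
                if 0 <= rr < rows and 0 <= cc < cols:
                    j = rr * cols + cc
                    if texture_ok[j]:
                        neigh.append(provisional[j])
        chosen, count = successive_abandonment(
            cand_disps[i],
            np.asarray(neigh).reshape(-1, 2),
            tol_floor=grid.abandonment_tol_floor,
            mad_factor=grid.abandonment_mad_factor,
            max_iter=grid.max_abandonments,
        )
        counts[i] = count
        if chosen is None:
            continue
        # subpixel refinement of the accepted integer peak
        surf = surfaces[i]
        dx_int, dy_int = cand_disps[i][chosen]
        cx, cy = centers[i]
        x0, y0 = origins[i]
        r_pk = int(round(dy_int + (cy - half) - y0))
        c_pk = int(round(dx_int + (cx - half) - x0))
        r_sub, c_sub, red = subpixel_peak(surf, (r_pk, c_pk))
        disps[i] = (x0 + c_sub - (cx - half), y0 + r_sub - (cy - half))
        peaks[i] = cand_peaks[i][chosen]
        valid[i] = True
        reduced[i] = red

    vels = np.zeros_like(disps)
    vels[valid] = disps[valid] * frame_a.pixel_size / dt
    t_mid = frame_a.timestamp + dt / 2.0
    return VectorField(
        centers=centers,
        displacements=disps,
        velocities=vels,
        peaks=peaks,
        valid=valid,
        abandonment_counts=counts,
        excluded=np.zeros(n, dtype=bool),
        t=t_mid,
        dt=dt,
        pixel_size=frame_a.pixel_size,
        grid_shape=(rows, cols),
        reduced_precision=reduced,
    )


def velocity_error_bound(pixel_error: float, pixel_size: float, dt: float) -> float:
    """Velocity uncertainty implied by a subpixel localization error.

    ``pixel_error * pixel_size / dt``: with the default calibration
    (21 px = 4.4 cm) and 300 frames/s, a 1/10 px error bounds the velocity
    error at about 6.3 cm/s.
    """
    if pixel_error < 0:
        raise InputError("pixel_error must be non-negative")
    if pixel_size <= 0 or dt <= 0:
        raise InputError("pixel_size and dt must be positive")
    return pixel_error * pixel_size / dt
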