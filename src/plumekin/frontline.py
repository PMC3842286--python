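"""Front-line reduction of vector fields.

The advancing margin (front line) of the expelled cloud carries the
fastest material; its horizontal velocity versus time is the series that
the exponential decay model is fitted to. Per frame, the front is taken as
the valid, non-excluded vector farthest from the mouth along the
expectoration direction. Large droplets (aerodynamic diameter above a
cutoff, default 300 um) sediment fast enough to leave the cloud within
fractions of a second; they are excluded on kinematic grounds — a
downward velocity exceeding the cutoff's Stokes settling velocity — since
individual particle sizes are below the spatial resolution of the
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, InputError
from .piv import VectorField

GRAVITY = 981.0  # cm/s^2
AIR_VISCOSITY = 1.8e-4  # g/(cm s), ~20-27 C
AIR_DENSITY = 1.2e-3  # g/cm^3
DEFAULT_DROPLET_CUTOFF_UM = 300.0
DEFAULT_DENSITY = 1.0  # g/cm^3, aqueous respiratory droplets


class SettlingResult(NamedTuple):
    velocity: float  # cm/s, terminal fall speed under Stokes drag
    reynolds: float  # particle Reynolds number at that speed
    beyond_stokes: bool  # True when Re > 1 (Stokes law unreliable)


def settling_velocity(
    diameter_um: float, density: float = DEFAULT_DENSITY
) -> SettlingResult:
    """Stokes terminal settling velocity of a spherical particle.

    v = rho d^2 g / (18 mu_air), with d the aerodynamic diameter. The
    ``beyond_stokes`` flag is raised when the particle Reynolds number
    exceeds 1, where the laminar-drag assumption starts to fail (relevant
    for the large-droplet regime, a few hundred um).
    """
    if diameter_um <= 0 or density <= 0:
        raise InputError("diameter and density must be positive")
    d_cm = diameter_um * 1e-4
    v = density * d_cm**2 * GRAVITY / (18.0 * AIR_VISCOSITY)
    re = AIR_DENSITY * v * d_cm / AIR_VISCOSITY
    return SettlingResult(velocity=v, reynolds=re, beyond_stokes=re > 1.0)


def exclude_fast_falling(
    field: VectorField,
    diameter_cutoff_um: float = DEFAULT_DROPLET_CUTOFF_UM,
    density: float = DEFAULT_DENSITY,
) -> VectorField:
    """Mark vectors falling faster than the cutoff's settling velocity.

    Pure filtering: retained vectors are untouched, excluded ones keep
    their values but carry the ``excluded`` flag (y is positive downward,
    so falling means vy > 0). Returns a new field.
    """
    if diameter_cutoff_um <= 0:
        raise InputError("diameter cutoff must be positive")
    v_cut = settling_velocity(diameter_cutoff_um, density).velocity
    excluded = field.excluded | (field.valid & (field.velocities[:, 1] > v_cut))
    return replace(field, excluded=excluded)


@dataclass(frozen=True)
class FrontlineSeries:
    """Per-frame (t, h, Vh) of the cloud's distal margin.

    h is the horizontal distance from the mouth in cm, Vh the horizontal
    velocity component in cm/s. Points are sorted by time and restricted
    to the analysis window.
    """

    t: np.ndarray  # s
    h: np.ndarray  # cm
    vh: np.ndarray  # cm/s
    window: tuple[float, float]
    label: str = ""

    def __post_init__(self):
        if not (np.all(np.diff(self.t) > 0)):
            raise InputError("front-line timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "h_cm": self.h, "vh_cms": self.vh})


def _horizontal(field: VectorField, mouth_x_px: float, direction: str):
    sign = {"+x": 1.0, "-x": -1.0}.get(direction)
    if sign is None:
        raise InputError("direction must be '+x' or '-x'")
    h = sign * (field.centers[:, 0] - mouth_x_px) * field.pixel_size
    vh = sign * field.velocities[:, 0]
    return h, vh


def extract_frontline(
    fields: Sequence[VectorField],
    mouth_x_px: float,
    direction: str = "+x",
    window: tuple[float, float] = (0.04, 0.20),
    label: str = "",
    quantile: float | None = None,
) -> FrontlineSeries:
    """Reduce per-frame vector fields to the distal-margin time series.

    Per frame inside the analysis window, selects the valid non-excluded
    vector with maximal horizontal distance h >= 0 from the mouth and
    emits (t, h, Vh). With ``quantile`` q set, the vectors in the top-q
    quantile of h are averaged instead of taking the single farthest one.
    Frames without a qualifying vector are skipped; an entirely empty
    result raises :class:`EmptySeriesError`.
    """
    t_min, t_max = window
    ts, hs, vhs = [], [], []
    for field in fields:
        if not (t_min <= field.t <= t_max):
            continue
        h, vh = _horizontal(field, mouth_x_px, direction)
        mask = field.valid & ~field.excluded & (h >= 0)
        if not mask.any():
            continue
        if quantile is None:
            i = int(np.argmax(np.where(mask, h, -np.inf)))
            ts.append(field.t)
            hs.append(h[i])
            vhs.append(vh[i])
        else:
            hm = h[mask]
            thr = np.quantile(hm, 1.0 - quantile)
            sel = mask & (h >= thr)
            ts.append(field.t)
            hs.append(float(np.mean(h[sel])))
            vhs.append(float(np.mean(vh[sel])))
    if not ts:
        raise EmptySeriesError(
            "no front-line points: every frame in the window "
            f"({t_min}-{t_max} s) lacks a valid, non-excluded vector; "
            "review the analysis window and validity/exclusion thresholds"
        )
    return FrontlineSeries(
        t=np.asarray(ts), h=np.asarray(hs), vh=np.asarray(vhs),
        window=(t_min, t_max), label=label,
    )


def export_velocity_map(
    fields: Sequence[VectorField], mouth_x_px: float, direction: str = "+x"
) -> pd.DataFrame:
    """Distance-time-velocity table over ALL valid vectors of all frames.

    One row per valid vector: (t_s, h_cm, vh_cms, vy_cms, peak, excluded).
    This is the full two-dimensional velocity-distribution view of the
    cloud, of which the front-line series is the per-frame maximal-h edge.
    """
    rows = []
    for field in fields:
        h, vh = _horizontal(field, mouth_x_px, direction)
        for i in np.flatnonzero(field.valid):
            rows.append(
                {
                    "t_s": field.t,
                    "h_cm": h[i],
                    "vh_cms": vh[i],
                    "vy_cms": field.velocities[i, 1],
                    "peak": field.peaks[i],
                    "excluded": bool(field.excluded[i]),
                }
            )
    return pd.DataFrame(
        rows, columns=["t_s", "h_cm", "vh_cms", "vy_cms", "peak", "excluded"]
    )
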