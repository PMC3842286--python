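"""Exponential velocity-decay model of the cloud front and reach estimates.

The front-line horizontal velocity is modelled as

    Vh(t) = A exp(-k t) + c

with amplitude A (cm/s), decay rate k (1/s) and offset c (cm/s). The
offset is the residual drift velocity the front settles to; for a sneeze
in calm air it is ~0, while for a cough recorded in a room with a
directed air-conditioning current it equals that current's speed.

Momentum loss is defined as the moment Vh drops to the ambient
convection speed v* (the insensible indoor airflow, ~15 cm/s on average):

    t* = (1/k) ln(A / (v* - c))

and the momentum-driven direct reach over [t0, t1] is the integral of Vh:

    reach = h0 + (A/k)(exp(-k t0) - exp(-k t1)) + c (t1 - t0).

The anchor (t0, h0) is explicit: the reach depends on where the model is
anchored in space, which a velocity-only fit does not determine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .errors import FitError, InputError
from .frontline import FrontlineSeries

NATURAL_CONVECTION_CMS = 15.0  # typical indoor insensible airflow, cm/s


@dataclass(frozen=True)
class DecayModel:
    """Fitted coefficients of Vh(t) = A exp(-k t) + c."""

    amplitude: float  # A, cm/s
    rate: float  # k, 1/s
    offset: float = 0.0  # c, cm/s
    rms: float = float("nan")  # fit residual RMS, cm/s
    n_points: int = 0

    def __post_init__(self):
        if self.amplitude <= 0 or self.rate <= 0 or self.offset < 0:
            raise InputError("require A > 0, k > 0, c >= 0")

    def to_dict(self) -> dict:
        return {
            "A_cms": self.amplitude,
            "k_per_s": self.rate,
            "c_cms": self.offset,
            "rms_cms": self.rms,
            "n": self.n_points,
        }


# Printed coefficients of the two reference events.
SNEEZE_MODEL = DecayModel(amplitude=1500.0, rate=22.0, offset=0.0)
COUGH_MODEL = DecayModel(amplitude=1100.0, rate=32.0, offset=27.0)


@dataclass(frozen=True)
class ReachResult:
    """Momentum-driven direct reach over [t_anchor, t_stop]."""

    v_threshold: float  # cm/s (nan when t_stop was given directly)
    t_stop: float  # s
    t_anchor: float  # s
    h_anchor: float  # cm
    reach: float  # cm

    def to_dict(self) -> dict:
        return {
            "v_threshold_cms": self.v_threshold,
            "t_stop_s": self.t_stop,
            "t_anchor_s": self.t_anchor,
            "h_anchor_cm": self.h_anchor,
            "reach_cm": self.reach,
        }


def evaluate_velocity(model: DecayModel, t):
    """Vh(t) = A exp(-k t) + c for scalar or array t >= 0."""
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise InputError("t must be non-negative")
    out = model.amplitude * np.exp(-model.rate * t_arr) + model.offset
    return float(out) if np.isscalar(t) else out


SeriesLike = Union[FrontlineSeries, tuple]


def _series_arrays(series: SeriesLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, FrontlineSeries):
        return series.t, series.vh
    t, vh = series
    return np.asarray(t, dtype=np.float64), np.asarray(vh, dtype=np.float64)


def fit_decay(
    series: SeriesLike,
    fix_offset: float | str | None = None,
    robust: bool = False,
) -> DecayModel:
    """Least-squares fit of Vh(t) = A exp(-k t) + c to a front-line series.

    ``fix_offset`` pins c: a number pins it exactly, ``'plateau'`` pins it
    to the mean Vh of the final 3 points (the late-time plateau the front
    settles onto), and None leaves c free (bounded at 0). Initialization
    is by linear regression of ln(Vh - c0) on t. ``robust=True`` switches
    to a soft-L1 loss for outlier-prone series.
    """
    t, vh = _series_arrays(series)
    if len(t) < 4:
        raise InputError(f"need at least 4 points to fit, got {len(t)}")
    if np.any(vh <= 0):
        raise InputError("all Vh values must be positive")

    if fix_offset == "plateau":
        c_pin: float | None = float(np.mean(vh[-3:]))
    elif fix_offset is None:
        c_pin = None
    else:
        c_pin = float(fix_offset)
        if c_pin < 0:
            raise InputError("fixed offset must be >= 0")

    # log-linear initialization
    c0 = c_pin if c_pin is not None else max(0.0, 0.8 * float(vh.min()))
    pos = vh - c0 > 0
    if pos.sum() >= 2:
        reg = linregress(t[pos], np.log(vh[pos] - c0))
        k0 = max(1e-3, -float(reg.slope))
        a0 = max(1e-3, float(np.exp(reg.intercept)))
    else:
        k0, a0 = 10.0, float(vh.max())

    loss = "soft_l1" if robust else "linear"
    if c_pin is not None:
        def resid(p):
            return p[0] * np.exp(-p[1] * t) + c_pin - vh

        res = least_squares(
            resid, x0=[a0, k0], bounds=([1e-9, 1e-9], [np.inf, np.inf]), loss=loss
        )
        a, k, c = res.x[0], res.x[1], c_pin
    else:
        def resid(p):
            return p[0] * np.exp(-p[1] * t) + p[2] - vh

        res = least_squares(
            resid,
            x0=[a0, k0, c0],
            bounds=([1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            loss=loss,
        )
        a, k, c = res.x

    if not res.success:
        raise FitError(
            f"decay fit did not converge (status {res.status}): "
            f"init A={a0:.3g}, k={k0:.3g}, c0={c0:.3g}; "
            f"final residual norm {np.linalg.norm(res.fun):.3g}"
        )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return DecayModel(float(a), float(k), float(c), rms=rms, n_points=len(t))


def momentum_loss_time(
    model: DecayModel, v_threshold: float = NATURAL_CONVECTION_CMS
) -> float:
    """Closed-form time at which Vh decays to the threshold velocity.

    t* = (1/k) ln(A / (v_threshold - c)). The threshold must exceed the
    offset c, otherwise the modelled velocity never reaches it.
    """
    if v_threshold <= model.offset:
        raise InputError(
            f"v_threshold ({v_threshold} cm/s) must exceed the model offset "
            f"({model.offset} cm/s): the velocity never decays below c"
        )
    return math.log(model.amplitude / (v_threshold - model.offset)) / model.rate


def direct_reach(
    model: DecayModel,
    t_start: float = 0.0,
    t_stop: float = math.inf,
    h_anchor: float = 0.0,
    v_threshold: float = float("nan"),
) -> ReachResult:
    """Closed-form integral of Vh over [t_start, t_stop], from h_anchor.

    reach = h_anchor + (A/k)(e^(-k t_start) - e^(-k t_stop)) + c (t_stop - t_start).
    An infinite t_stop is allowed only for c = 0 (otherwise the drift term
    diverges).
    """
    if t_start < 0 or t_stop < t_start:
        raise InputError("require 0 <= t_start <= t_stop")
    a, k, c = model.amplitude, model.rate, model.offset
    decay_term = (a / k) * (math.exp(-k * t_start) - math.exp(-k * t_stop))
    if math.isinf(t_stop):
        if c != 0:
            raise InputError("infinite t_stop diverges for c > 0")
        drift_term = 0.0
    else:
        drift_term = c * (t_stop - t_start)
    return ReachResult(
        v_threshold=v_threshold,
        t_stop=t_stop,
        t_anchor=t_start,
        h_anchor=h_anchor,
        reach=h_anchor + decay_term + drift_term,
    )


def reach_at_momentum_loss(
    model: DecayModel,
    v_threshold: float = NATURAL_CONVECTION_CMS,
    t_anchor: float = 0.0,
    h_anchor: float = 0.0,
) -> ReachResult:
    """Direct reach integrated from the anchor to the momentum-loss time."""
    t_stop = momentum_loss_time(model, v_threshold)
    return direct_reach(
        model, t_start=t_anchor, t_stop=max(t_stop, t_anchor),
        h_anchor=h_anchor, v_threshold=v_threshold,
    )
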