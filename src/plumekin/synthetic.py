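"""Synthetic expiratory-cloud generator with exact ground truth.

Emulates a high-speed lateral recording of a particle cloud expelled
horizontally from a mouth: the front-line horizontal velocity follows
Vh(t) = A exp(-k t) + c, interior particles move with per-particle scale
factors of that law, large droplets additionally sediment at their Stokes
settling velocity, and once a particle's decaying velocity component
drops below a momentum floor it switches to a diffusive random walk plus
a uniform convection drift. Frames are rendered as Gaussian intensity
blobs over additive sensor noise.

Positions before the momentum-loss switch are evaluated from the closed
form of the integrated decay law (not time-stepped), so ground truth is
exact to machine precision there.

Randomness: one generator seeded from ``seed`` drives all trajectory and
appearance draws, in this order: velocity scale factors, initial x
jitter, initial y spread, blob radii, blob peak intensities, diffusion
increments. Frame noise uses a child stream spawned from the same seed so
rendering never perturbs trajectory draws.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .frontline import settling_velocity
from .imaging import DEFAULT_PIXEL_SIZE, FrameSequence


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the simulated cloud and its rendering."""

    amplitude: float = 1500.0  # A, cm/s
    decay_rate: float = 22.0  # k, 1/s
    offset: float = 0.0  # c, cm/s
    frame_rate: float = 300.0  # frames/s
    frame_width: int = 640  # px
    frame_height: int = 400  # px
    pixel_size: float = DEFAULT_PIXEL_SIZE  # cm/px
    duration: float = 0.4  # s
    n_particles: int = 200  # fine particles
    particle_radius_range: tuple[float, float] = (1.2, 2.5)  # px (Gaussian sigma)
    intensity_range: tuple[float, float] = (80.0, 220.0)  # blob peak, 8-bit units
    noise_sd: float = 2.0  # additive sensor noise, 8-bit units
    convection_velocity: float = 0.0  # cm/s, post-momentum-loss drift
    n_large_droplets: int = 0
    large_droplet_diameter: float = 400.0  # um
    droplet_density: float = 1.0  # g/cm^3
    diffusion_sd: float = 5.0  # cm/sqrt(s), post-momentum-loss random walk
    momentum_floor: float = 15.0  # cm/s; 0 disables the diffusion switch
    x_jitter: float = 4.0  # cm, interior particles start in [-x_jitter, 0]
    y_spread: float = 2.0  # cm, s.d. of initial vertical scatter
    mouth_position: tuple[float, float] = (30.0, 120.0)  # (x, y) px
    seed: int = 0

    def __post_init__(self):
        if self.amplitude <= 0 or self.decay_rate <= 0 or self.offset < 0:
            raise ConfigError("require A > 0, k > 0, c >= 0")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ConfigError("frame_rate and pixel_size must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.particle_radius_range[0] < 1.0:
            raise ConfigError("particle radii must be >= 1 px")
        n_exact = self.duration * self.frame_rate
        if abs(n_exact - round(n_exact)) > 1e-6:
            raise ConfigError(
                f"duration*frame_rate = {n_exact} is not an integer frame count"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sneeze_config(**overrides) -> SynthConfig:
    """Sneeze-like event: A=1500 cm/s, k=22 /s, c=0, calm room."""
    base = dict(
        amplitude=1500.0, decay_rate=22.0, offset=0.0,
        convection_velocity=0.0, n_large_droplets=3,
    )
    base.update(overrides)
    return SynthConfig(**base)


def cough_config(**overrides) -> SynthConfig:
    """Cough-like event: A=1100 cm/s, k=32 /s, c=27 cm/s.

    The offset equals the room's directed convection current, so the
    post-momentum-loss drift is continuous with the decay law.
    """
    base = dict(
        amplitude=1100.0, decay_rate=32.0, offset=27.0,
        convection_velocity=27.0, n_large_droplets=0,
    )
    base.update(overrides)
    return SynthConfig(**base)


@dataclass
class GroundTruth:
    """Exact trajectories and front-line kinematics of a simulated cloud."""

    times: np.ndarray  # (n_frames,) s
    positions: np.ndarray  # (n_total, n_frames, 2) cm, origin at mouth
    classes: np.ndarray  # (n_total,) 'fine' | 'large-droplet'
    scales: np.ndarray  # (n_total,) velocity scale factor in (0, 1]
    switch_times: np.ndarray  # (n_total,) s, momentum-loss switch (inf if never)
    sigmas_px: np.ndarray  # (n_total,) blob Gaussian sigma
    amplitudes: np.ndarray  # (n_total,) blob peak intensity
    front_position: np.ndarray  # (n_frames,) cm
    front_velocity: np.ndarray  # (n_frames,) cm/s
    config: SynthConfig

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls, config: SynthConfig) -> "GroundTruth":
        n = config.n_frames
        t = np.arange(n) / config.frame_rate
        z = np.zeros(0)
        return cls(
            times=t,
            positions=np.zeros((0, n, 2)),
            classes=np.array([], dtype=object),
            scales=z, switch_times=z, sigmas_px=z, amplitudes=z,
            front_position=np.zeros(n), front_velocity=np.zeros(n),
            config=config,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_particles):
            for j, t in enumerate(self.times):
                rows.append(
                    (i, self.classes[i], t,
                     self.positions[i, j, 0], self.positions[i, j, 1])
                )
        return pd.DataFrame(
            rows, columns=["particle_id", "class", "t_s", "x_cm", "y_cm"]
        )

    def save(self, directory: str, prefix: str = "truth") -> None:
        os.makedirs(directory, exist_ok=True)
        self.to_dataframe().to_csv(
            os.path.join(directory, f"{prefix}_trajectories.csv"), index=False
        )
        with open(os.path.join(directory, f"{prefix}_config.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)


def _integrated_law(config: SynthConfig, t: np.ndarray) -> np.ndarray:
    # closed-form displacement of the unscaled decay law from 0 to t
    a, k, c = config.amplitude, config.decay_rate, config.offset
    return (a / k) * (1.0 - np.exp(-k * t)) + c * t


def simulate_trajectories(config: SynthConfig) -> GroundTruth:
    """Simulate all particle trajectories at the frame timestamps.

    Particle 0 is the front particle: scale factor exactly 1 and zero
    initial offset, so before momentum loss it moves with the full law
    Vh(t) = A exp(-k t) + c and stays at the maximal x of the cloud.
    """
    if config.duration <= 0:
        raise ConfigError("duration must be positive")
    if config.n_particles == 0:
        raise ConfigError("n_particles must be >= 1")

    rng = np.random.default_rng(config.seed)
    n_fine, n_drop = config.n_particles, config.n_large_droplets
    n_total = n_fine + n_drop
    n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate
    dt = config.dt
    a, k, c = config.amplitude, config.decay_rate, config.offset

    # draw order: scales, x jitter, y spread, radii, intensities, diffusion
    scales = rng.uniform(0.5, 1.0, size=n_total)
    scales[0] = 1.0
    x0 = rng.uniform(-config.x_jitter, 0.0, size=n_total)
    x0[0] = 0.0
    y0 = rng.normal(0.0, config.y_spread, size=n_total)
    y0[0] = 0.0
    sigmas = rng.uniform(*config.particle_radius_range, size=n_total)
    amps = rng.uniform(*config.intensity_range, size=n_total)

    # momentum-loss switch: when the particle's decaying velocity component
    # s*A*exp(-k t) falls below the floor
    floor = config.momentum_floor
    if floor > 0:
        with np.errstate(divide="ignore"):
            t_switch = np.where(
                scales * a > floor, np.log(scales * a / floor) / k, 0.0
            )
    else:
        t_switch = np.full(n_total, np.inf)
    # large droplets are inertial: no diffusion switch
    if n_drop:
        t_switch[n_fine:] = np.inf

    # deterministic part, evaluated analytically up to min(t, t_switch)
    t_grid = np.broadcast_to(t, (n_total, n_frames))
    t_eff = np.minimum(t_grid, t_switch[:, None])
    x = x0[:, None] + scales[:, None] * _integrated_law(config, t_eff)
    y = np.broadcast_to(y0[:, None], (n_total, n_frames)).copy()

    # post-switch: convection drift + diffusive random walk
    past = t_grid > t_switch[:, None]
    drift = np.zeros_like(x)
    drift[past] = config.convection_velocity * (t_grid - t_switch[:, None])[past]
    x = x + drift
    if config.diffusion_sd > 0 and np.isfinite(t_switch).any():
        steps = rng.normal(
            0.0, config.diffusion_sd * np.sqrt(dt), size=(n_total, n_frames, 2)
        )
        steps[~past] = 0.0  # increments only accrue after the switch
        walk = np.cumsum(steps, axis=1)
        x = x + walk[:, :, 0]
        y = y + walk[:, :, 1]

    # large droplets fall at their Stokes settling velocity throughout
    if n_drop:
        v_settle = settling_velocity(
            config.large_droplet_diameter, config.droplet_density
        ).velocity
        y[n_fine:] += v_settle * t

    positions = np.stack([x, y], axis=-1)

    front_velocity = np.where(
        t <= t_switch[0],
        a * np.exp(-k * t) + c,
        config.convection_velocity,
    )
    classes = np.array(
        ["fine"] * n_fine + ["large-droplet"] * n_drop, dtype=object
    )
    return GroundTruth(
        times=t,
        positions=positions,
        classes=classes,
        scales=scales,
        switch_times=t_switch,
        sigmas_px=sigmas,
        amplitudes=amps,
        front_position=x[0].copy(),
        front_velocity=front_velocity,
        config=config,
    )


def render_frames(truth: GroundTruth, config: SynthConfig | None = None) -> FrameSequence:
    """Render trajectories as 8-bit grayscale frames.

    Each particle becomes an isotropic Gaussian blob at its pixel position
    (continuous Gaussian evaluated at pixel centres, so the blob centroid
    tracks the true subpixel position); additive Gaussian sensor noise of
    s.d. ``noise_sd`` is applied and the result clipped to [0, 255].
    Particles outside the frame are simply not rendered.
    """
    config = config or truth.config
    h, w = config.frame_height, config.frame_width
    mx, my = config.mouth_position
    n_frames = config.n_frames
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0]
    )
    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    for j in range(n_frames):
        canvas = np.zeros((h, w), dtype=np.float64)
        for i in range(truth.n_particles):
            px = mx + truth.positions[i, j, 0] / config.pixel_size
            py = my + truth.positions[i, j, 1] / config.pixel_size
            s = truth.sigmas_px[i]
            r = int(np.ceil(4.0 * s))
            if px < -r or px > w - 1 + r or py < -r or py > h - 1 + r:
                continue
            xlo, xhi = max(0, int(np.floor(px)) - r), min(w, int(np.ceil(px)) + r + 1)
            ylo, yhi = max(0, int(np.floor(py)) - r), min(h, int(np.ceil(py)) + r + 1)
            xs = np.arange(xlo, xhi)
            ys = np.arange(ylo, yhi)
            gx = np.exp(-((xs - px) ** 2) / (2.0 * s**2))
            gy = np.exp(-((ys - py) ** 2) / (2.0 * s**2))
            canvas[ylo:yhi, xlo:xhi] += truth.amplitudes[i] * np.outer(gy, gx)
        if config.noise_sd > 0:
            canvas += noise_rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[j] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return FrameSequence(
        data=frames,
        dt=config.dt,
        pixel_size=config.pixel_size,
        mouth_position=(mx, my),
    )
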