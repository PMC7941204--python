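"""Render simulated event logs into observable data.

Produces multi-channel kymographs (RPA-coated ssDNA in the blue channel,
fluorophore-labeled protomers in green, mediator caps as red
diffraction-limited spots), coverage-coupled force traces, and
photobleaching staircase traces.  Imaging defaults follow a confocal
line-scanning instrument: 100 nm pixels, 1.5 s inter-frame wait plus the
scan time itself per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .mechanics import NM_PER_NT_AT_IMAGING_FORCE
from .sim_core import EventLog, replay_occupancy

__all__ = [
    "RenderConfig",
    "Kymograph",
    "ForceTrace",
    "IntensityTrace",
    "render_kymograph",
    "render_force",
    "render_bleach_trace",
]

PIXEL_DWELL_S = 1e-4  # 0.1 ms/pixel confocal dwell
INTERFRAME_WAIT_S = 1.5


@dataclass
class RenderConfig:
    pixel_size_nm: float = 100.0
    psf_sigma_nm: float = 150.0
    nm_per_nt: float = NM_PER_NT_AT_IMAGING_FORCE
    unit_brightness: float = 100.0  # expected photons per fluorophore per line
    rpa_brightness: float = 100.0  # expected photons per fully-uncovered pixel
    bleach_rate_per_min: float = 0.0
    shot_noise: bool = True
    read_noise_sigma: float = 20.0
    labeled_fraction: float = 1.0  # protomers carrying a fluorophore
    cap_spot_brightness: float = 2000.0
    #: expected number of transient non-cap red spots per frame, placed
    #: uniformly on uncovered ssDNA (background mediator binding)
    bg_spot_rate_per_frame: float = 0.0
    interframe_wait_s: float = INTERFRAME_WAIT_S
    pixel_dwell_s: float = PIXEL_DWELL_S

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.pixel_dwell_s < 0 or self.interframe_wait_s < 0:
            raise ValueError("dwell/wait times must be >= 0")


@dataclass
class Kymograph:
    """Multi-channel position x time intensity image with calibration."""

    channels: dict[str, np.ndarray]  # each (n_pixels, n_frames)
    pixel_size_nm: float
    line_time_s: float
    orientation: str = "5p-left"  # which image edge is the ssDNA 5' end
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree in shape: {shapes}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.line_time_s <= 0:
            raise ValueError("line_time_s must be > 0")
        for name, ch in self.channels.items():
            if np.any(ch < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def n_pixels(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.line_time_s

    def flipped(self) -> "Kymograph":
        """Position axis reversed, with orientation metadata updated."""
        orient = "5p-right" if self.orientation == "5p-left" else "5p-left"
        return Kymograph(
            channels={k: v[::-1].copy() for k, v in self.channels.items()},
            pixel_size_nm=self.pixel_size_nm,
            line_time_s=self.line_time_s,
            orientation=orient,
            metadata=dict(self.metadata),
        )


@dataclass
class ForceTrace:
    time_s: np.ndarray
    force_pN: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if not np.all(np.isfinite(self.force_pN)):
            raise ValueError("force must be finite")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class IntensityTrace:
    time_s: np.ndarray
    intensity: np.ndarray
    true_fluorophores: np.ndarray | None = None  # per-frame ground truth
    true_change_points: list[int] | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)


def _pixel_coverage(intervals, n_px: int, nt_per_px: float) -> np.ndarray:
    """Fraction of each pixel covered by filament, from nt intervals."""
    cov = np.zeros(n_px)
    for lo, hi in intervals:
        a, b = lo / nt_per_px, hi / nt_per_px
        i0, i1 = int(np.floor(a)), min(int(np.ceil(b)), n_px)
        for i in range(i0, i1):
            cov[i] += max(0.0, min(i + 1, b) - max(i, a))
    return np.clip(cov, 0.0, 1.0)


def render_kymograph(
    log: EventLog,
    config: RenderConfig | None = None,
    n_frames: int | None = None,
    frame_interval_s: float | None = None,
    seed: int = 0,
) -> Kymograph:
    """Render an event log as a blue/green/red kymograph.

    Blue: intensity proportional to uncovered ssDNA per pixel (filaments
    appear dark).  Green: labeled protomers, each an expected
    ``unit_brightness`` placed at its lattice position, subject to
    per-fluorophore exponential bleaching.  Red: capped 5' ends as
    diffraction-limited spots.  A 1-D Gaussian PSF acts along position;
    Poisson shot noise and Gaussian read noise are then applied.
    """
    cfg = config or RenderConfig()
    rng = np.random.default_rng(seed)
    sim = log.config
    nt_per_px = cfg.pixel_size_nm / cfg.nm_per_nt
    n_px = int(np.ceil(sim.lattice_length_nt / nt_per_px))
    # one line = scan + inter-frame wait; a coarser cadence may be
    # requested (e.g. 30-s dipping frames), which then IS the line time
    line_time_s = cfg.interframe_wait_s + n_px * cfg.pixel_dwell_s
    if frame_interval_s is not None:
        if frame_interval_s < line_time_s:
            raise ValueError("frame_interval_s shorter than one line scan")
        line_time_s = frame_interval_s
    if n_frames is None:
        n_frames = max(2, int(sim.duration_min * 60.0 / line_time_s))
    frame_times_min = np.arange(n_frames) * line_time_s / 60.0

    # fluorophore bookkeeping: each deposited protomer gets a label flag
    # and a bleach time drawn at deposition
    blue = np.zeros((n_px, n_frames))
    green = np.zeros((n_px, n_frames))
    red = np.zeros((n_px, n_frames))
    psf_sigma_px = cfg.psf_sigma_nm / cfg.pixel_size_nm

    # Protomer identity: a protomer occupies a fixed (filament, position)
    # slot for its whole bound lifetime (growth and bursts act only at
    # the ends), so label and bleach-clock draws key on the slot.  A slot
    # re-deposited after a burst keeps its first clock — an approximation
    # that slightly overstates bleaching of re-added protomers.
    events = log.events
    slot_draws: dict[tuple[int, int], tuple[bool, float]] = {}
    for e in events:
        if e.kind in ("nucleate", "add"):
            for k in range(e.protomer_count):
                key = (e.filament_id, e.position_nt + k * sim.footprint_nt)
                if key not in slot_draws:
                    labeled = rng.uniform() < cfg.labeled_fraction
                    if cfg.bleach_rate_per_min > 0:
                        bleach_t = e.time_min + rng.exponential(1.0 / cfg.bleach_rate_per_min)
                    else:
                        bleach_t = np.inf
                    slot_draws[key] = (labeled, bleach_t)

    cap_state: dict[int, bool] = {}
    cap_changes = [(e.time_min, e.filament_id, e.kind == "cap_bind")
                   for e in events if e.kind in ("cap_bind", "cap_release")]

    for fi, t in enumerate(frame_times_min):
        live = replay_occupancy(events, t, sim.footprint_nt)
        cov = _pixel_coverage(list(live.values()), n_px, nt_per_px)
        blue[:, fi] = cfg.rpa_brightness * (1.0 - cov)

        # green: protomers currently bound, labeled, and unbleached
        for fid, (lo, hi) in live.items():
            for pos_nt in range(lo, hi, sim.footprint_nt):
                labeled, bleach_t = slot_draws[(fid, pos_nt)]
                if not labeled or bleach_t <= t:
                    continue
                px = int(pos_nt / nt_per_px)
                if 0 <= px < n_px:
                    green[px, fi] += cfg.unit_brightness

        # red: capped 5' ends
        for tt, fid, bound in cap_changes:
            if tt > t:
                break
            cap_state[fid] = bound
        for fid, capped in cap_state.items():
            iv = live.get(fid)
            if capped and iv is not None:
                px = int(iv[0] / nt_per_px)
                if 0 <= px < n_px:
                    red[px, fi] += cfg.cap_spot_brightness
        if cfg.bg_spot_rate_per_frame > 0:
            covered = np.zeros(sim.lattice_length_nt, dtype=bool)
            for lo, hi in live.values():
                covered[lo:hi] = True
            free_nt = np.nonzero(~covered)[0]
            for _ in range(rng.poisson(cfg.bg_spot_rate_per_frame)):
                if free_nt.size == 0:
                    break
                pos = free_nt[rng.integers(0, free_nt.size)]
                px = int(pos / nt_per_px)
                if 0 <= px < n_px:
                    red[px, fi] += cfg.cap_spot_brightness

    if psf_sigma_px > 0:
        for img in (blue, green, red):
            img[:] = gaussian_filter1d(img, psf_sigma_px, axis=0, mode="reflect")
    if cfg.shot_noise:
        blue = rng.poisson(blue).astype(float)
        green = rng.poisson(green).astype(float)
        red = rng.poisson(red).astype(float)
    if cfg.read_noise_sigma > 0:
        shape = blue.shape
        blue = blue + rng.normal(0, cfg.read_noise_sigma, shape)
        green = green + rng.normal(0, cfg.read_noise_sigma, shape)
        red = red + rng.normal(0, cfg.read_noise_sigma, shape)
    blue, green, red = (np.clip(a, 0, None) for a in (blue, green, red))

    return Kymograph(
        channels={"blue": blue, "green": green, "red": red},
        pixel_size_nm=cfg.pixel_size_nm,
        line_time_s=line_time_s,
        orientation="5p-left",
        metadata={"seed": seed, "sim_seed": log.seed, "n_frames": n_frames},
    )


def render_force(
    log: EventLog,
    f_bare_pN: float = 15.0,
    f_full_pN: float = 1.0,
    sample_rate_hz: float = 78.0,
    noise_sigma_pN: float = 0.0,
    seed: int = 0,
) -> ForceTrace:
    """Force trace linear in coverage fraction between bare and fully
    coated ssDNA (filament formation relaxes the force)."""
    rng = np.random.default_rng(seed)
    duration_s = log.config.duration_min * 60.0
    n = max(2, int(duration_s * sample_rate_hz))
    time_s = np.arange(n) / sample_rate_hz
    cov = np.array(
        [o["coverage"] for o in _coverage_at(log, time_s / 60.0)]
    )
    force = f_bare_pN + cov * (f_full_pN - f_bare_pN)
    if noise_sigma_pN > 0:
        force = force + rng.normal(0, noise_sigma_pN, n)
    return ForceTrace(time_s=time_s, force_pN=force, sample_rate_hz=sample_rate_hz)


def _coverage_at(log: EventLog, times_min: np.ndarray) -> list[dict]:
    # import here to avoid cycle at module import time
    from .sim_core import occupancy_timeseries

    return occupancy_timeseries(log, times_min)


def render_bleach_trace(
    n_fluorophores: int,
    unit_intensity: float = 100.0,
    bleach_rate_per_s: float = 0.1,
    noise_sigma: float = 0.0,
    n_frames: int = 200,
    frame_time_s: float = 0.1,
    seed: int = 0,
) -> IntensityTrace:
    """Photobleaching staircase with exponential single-fluorophore
    bleach times; ground-truth change points are recorded."""
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    rng = np.random.default_rng(seed)
    time_s = np.arange(n_frames) * frame_time_s
    if bleach_rate_per_s > 0:
        bleach_times = rng.exponential(1.0 / bleach_rate_per_s, size=n_fluorophores)
    else:
        bleach_times = np.full(n_fluorophores, np.inf)
    counts = (time_s[:, None] < bleach_times[None, :]).sum(axis=1)
    intensity = counts * unit_intensity
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0, noise_sigma, n_frames)
    cps = [int(i) for i in np.nonzero(np.diff(counts))[0] + 1]
    return IntensityTrace(
        time_s=time_s,
        intensity=intensity,
        true_fluorophores=counts,
        true_change_points=cps,
    )
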