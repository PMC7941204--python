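"""Assembly kinetics from kymographs.

Four measurements: (1) normalized displacement decay of the
ssDNA-binding-protein channel fitted to a single exponential; (2) the
nucleation-counting image pipeline (contrast normalize -> 25-frame median
filter along time -> invert -> 5-px boxcar smoothing along position then
time -> per-frame peak detection -> saturating-exponential fit of
counts); (3) growth-rate slopes of displaced-signal borders with
direction assignment; (4) block-mean force downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import linregress

from .mechanics import nm_rate_to_nt_rate
from .sim_render import ForceTrace, Kymograph

__all__ = [
    "DisplacementTrace",
    "NucleationSeries",
    "GrowthEvent",
    "quantify_displacement",
    "count_filaments_over_time",
    "measure_growth_rates",
    "downsample_force",
]

MEDIAN_WINDOW_FRAMES = 25
SMOOTH_WINDOW_PX = 5


@dataclass
class DisplacementTrace:
    time_min: np.ndarray
    normalized_intensity: np.ndarray
    rate_per_min: float
    rate_stderr: float
    baseline: float
    half_time_min: float


@dataclass
class NucleationSeries:
    time_min: np.ndarray
    counts: np.ndarray
    a_max: float
    rate_per_min: float
    a_max_stderr: float
    rate_stderr: float
    degenerate: bool = False


@dataclass
class GrowthEvent:
    filament_id: int
    edge: str  # "5p-side" | "3p-side"
    frames: np.ndarray
    positions_nm: np.ndarray
    slope_nm_per_min: float
    slope_nt_per_min: float
    direction: str  # "3'->5'" | "5'->3'"


class DegenerateFitError(RuntimeError):
    pass


def quantify_displacement(kymo: Kymograph, channel: str = "blue") -> DisplacementTrace:
    """Summed channel intensity per frame, normalized to the mean of the
    first 3 frames, fitted to y = (1 - b) exp(-k t) + b.

    ``half_time_min`` is defined as ln(2)/k under this model.
    """
    if channel not in kymo.channels:
        raise KeyError(f"channel {channel!r} not present")
    img = kymo.channels[channel]
    total = img.sum(axis=0)
    norm = total / np.mean(total[:3])
    t = kymo.frame_times_s / 60.0

    def model(tt, k, b):
        return (1 - b) * np.exp(-k * tt) + b

    try:
        popt, pcov = curve_fit(
            model, t, norm, p0=[0.1, 0.0], bounds=([0.0, 0.0], [np.inf, 1.0]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise DegenerateFitError(f"displacement fit did not converge: {exc}") from exc
    k, b = popt
    k_err = float(np.sqrt(pcov[0, 0]))
    half = np.log(2) / k if k > 0 else np.inf
    return DisplacementTrace(
        time_min=t,
        normalized_intensity=norm,
        rate_per_min=float(k),
        rate_stderr=k_err,
        baseline=float(b),
        half_time_min=float(half),
    )


def _contrast_normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def nucleation_image_pipeline(
    img: np.ndarray,
    median_window: int = MEDIAN_WINDOW_FRAMES,
    smooth_window: int = SMOOTH_WINDOW_PX,
) -> np.ndarray:
    """Steps 1-4 of the nucleation-counting pipeline: contrast
    normalization, median filter along time, inversion, boxcar smoothing
    along position then time.  ``img`` is (position, time)."""
    out = _contrast_normalize(img)
    out = median_filter(out, size=(1, median_window), mode="reflect")
    out = 1.0 - out
    out = uniform_filter1d(out, smooth_window, axis=0, mode="reflect")
    out = uniform_filter1d(out, smooth_window, axis=1, mode="reflect")
    return out


def count_filaments_over_time(
    kymo: Kymograph,
    channel: str = "blue",
    median_window: int = MEDIAN_WINDOW_FRAMES,
    smooth_window: int = SMOOTH_WINDOW_PX,
    prominence_frac: float = 0.2,
    min_separation_px: int = 3,
) -> NucleationSeries:
    """Per-frame filament counts from the inverted, filtered channel,
    fitted to y = A_max (1 - exp(-k t))."""
    img = kymo.channels[channel]
    if img.shape[1] < median_window:
        raise ValueError(f"need >= {median_window} frames, got {img.shape[1]}")
    proc = nucleation_image_pipeline(img, median_window, smooth_window)
    t = kymo.frame_times_s / 60.0
    counts = np.zeros(img.shape[1], dtype=int)
    for fi in range(img.shape[1]):
        # prominence is a fraction of the contrast-normalized full scale
        # (1.0), so noise-only frames with a small dynamic range yield no
        # peaks
        peaks, _ = find_peaks(
            proc[:, fi], prominence=prominence_frac, distance=min_separation_px
        )
        counts[fi] = len(peaks)

    if counts.max() == 0:
        return NucleationSeries(t, counts, 0.0, 0.0, 0.0, 0.0, degenerate=True)

    def model(tt, a, k):
        return a * (1 - np.exp(-k * tt))

    try:
        popt, pcov = curve_fit(
            model, t, counts.astype(float),
            p0=[max(counts.max(), 1.0), 0.5],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
        )
        perr = np.sqrt(np.diag(pcov))
        return NucleationSeries(
            t, counts, float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1])
        )
    except RuntimeError:
        return NucleationSeries(t, counts, 0.0, 0.0, 0.0, 0.0, degenerate=True)


def _half_depth_edges(profile: np.ndarray, lo_px: int, hi_px: int) -> tuple[float, float] | None:
    """Subpixel half-depth crossings of a dark region inside [lo_px, hi_px].

    The region's depth is measured against the local background (profile
    maximum in the window); returns (left_edge, right_edge) in px or None
    if no depression is resolvable.
    """
    win = profile[lo_px:hi_px]
    if win.size < 3:
        return None
    bg = win.max()
    i_min = int(np.argmin(win))
    depth = bg - win[i_min]
    if depth <= 0:
        return None
    half = bg - depth / 2.0

    left = None
    for i in range(i_min, 0, -1):
        if win[i - 1] >= half >= win[i]:
            frac = (half - win[i]) / (win[i - 1] - win[i])
            left = i - frac
            break
    right = None
    for i in range(i_min, win.size - 1):
        if win[i + 1] >= half >= win[i]:
            frac = (half - win[i]) / (win[i + 1] - win[i])
            right = i + frac
            break
    if left is None or right is None:
        return None
    return (lo_px + left, lo_px + right)


def measure_growth_rates(
    kymo: Kymograph,
    filament_regions: list[dict],
    channel: str = "blue",
    smooth_window: int = SMOOTH_WINDOW_PX,
    min_frames: int = 5,
) -> list[GrowthEvent]:
    """Edge slopes of dark (displaced-signal) regions.

    Each region dict gives ``filament_id``, pixel bounds ``lo_px``/
    ``hi_px`` and frame bounds ``frame_lo``/``frame_hi``.  Edges are
    localized per frame at the half-depth crossing of the smoothed
    profile; the slope comes from a least-squares line in nm/min.
    Frames where an edge is lost (e.g. merging) are dropped, never
    extrapolated.
    """
    img = kymo.channels[channel]
    events: list[GrowthEvent] = []
    five_prime_left = kymo.orientation == "5p-left"
    for region in filament_regions:
        fid = region.get("filament_id", -1)
        lo_px = int(region["lo_px"])
        hi_px = int(region["hi_px"])
        f0 = int(region.get("frame_lo", 0))
        f1 = int(region.get("frame_hi", img.shape[1]))
        frames, lefts, rights = [], [], []
        for fi in range(f0, min(f1, img.shape[1])):
            prof = uniform_filter1d(img[:, fi], smooth_window, mode="reflect")
            edges = _half_depth_edges(prof, lo_px, hi_px)
            if edges is None:
                continue
            frames.append(fi)
            lefts.append(edges[0])
            rights.append(edges[1])
        if len(frames) < min_frames:
            continue
        frames_a = np.asarray(frames)
        t_min = frames_a * kymo.line_time_s / 60.0
        for side, positions in (("left", np.asarray(lefts)), ("right", np.asarray(rights))):
            pos_nm = positions * kymo.pixel_size_nm
            res = linregress(t_min, pos_nm)
            slope = float(res.slope)
            is_5p_side = (side == "left") == five_prime_left
            edge = "5p-side" if is_5p_side else "3p-side"
            # a growing 5'-side edge moves toward the 5' lattice end
            direction = "3'->5'" if is_5p_side else "5'->3'"
            events.append(
                GrowthEvent(
                    filament_id=fid,
                    edge=edge,
                    frames=frames_a,
                    positions_nm=pos_nm,
                    slope_nm_per_min=slope,
                    slope_nt_per_min=float(nm_rate_to_nt_rate(abs(slope))) * np.sign(slope),
                    direction=direction,
                )
            )
    return events


def downsample_force(trace: ForceTrace, target_hz: float = 3.0) -> ForceTrace:
    """Non-overlapping block means; a trailing partial block is dropped."""
    if target_hz > trace.sample_rate_hz:
        raise ValueError(
            f"target rate {target_hz} Hz exceeds source rate {trace.sample_rate_hz} Hz"
        )
    block = int(round(trace.sample_rate_hz / target_hz))
    n_blocks = len(trace.force_pN) // block
    if n_blocks == 0:
        raise ValueError("trace shorter than one block")
    f = trace.force_pN[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    t = trace.time_s[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return ForceTrace(time_s=t, force_pN=f, sample_rate_hz=target_hz)
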