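"""Photobleaching step analysis.

Change points are placed by greedy binary segmentation maximizing the
Gaussian likelihood of a piecewise-constant model, accepted while the
Bayesian information criterion improves.  Unit fluorophore intensity is
calibrated from the step-size histogram with a two-component Gaussian
whose second mean is constrained to twice the first (double-bleach
frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .sim_render import IntensityTrace

__all__ = [
    "StepModel",
    "Calibration",
    "ClusterTrack",
    "find_steps",
    "calibrate_unit",
    "count_protomers",
    "detect_growth",
]


@dataclass
class StepModel:
    change_points: list[int]  # frame index of the first frame after each step
    levels: list[float]  # segment means, len = len(change_points) + 1
    log_likelihood: float
    bic: float

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.change_points, self.change_points[1:])):
            raise ValueError("change points must be strictly increasing")
        if len(self.levels) != len(self.change_points) + 1:
            raise ValueError("#levels must equal #change points + 1")

    @property
    def step_sizes(self) -> np.ndarray:
        """Level differences (positive for downward bleaching steps)."""
        lv = np.asarray(self.levels)
        return lv[:-1] - lv[1:]

    @property
    def n_steps(self) -> int:
        return len(self.change_points)


def _sse(prefix: np.ndarray, prefix2: np.ndarray, a: int, b: int) -> float:
    """Sum of squared deviations of y[a:b] around its mean, O(1)."""
    n = b - a
    s = prefix[b] - prefix[a]
    s2 = prefix2[b] - prefix2[a]
    return max(s2 - s * s / n, 0.0)


def _best_split(prefix, prefix2, a: int, b: int) -> tuple[int, float] | None:
    """Best single change point in [a, b); returns (cp, sse_after)."""
    if b - a < 2:
        return None
    best_cp, best = -1, np.inf
    for cp in range(a + 1, b):
        cost = _sse(prefix, prefix2, a, cp) + _sse(prefix, prefix2, cp, b)
        if cost < best:
            best, best_cp = cost, cp
    return best_cp, best


def find_steps(
    trace: IntensityTrace | np.ndarray,
    min_frames: int = 10,
    penalty_per_cp: float = 5.0,
) -> StepModel:
    """Fit a piecewise-constant step model by binary segmentation.

    Splits are accepted while the BIC of the Gaussian model improves;
    each change point costs ``penalty_per_cp * ln(N)``.  The default
    penalty is stricter than the textbook 2 ln(N) because greedy binary
    segmentation tends to over-split at low SNR.  Zero steps is a valid
    result.
    """
    y = np.asarray(trace.intensity if isinstance(trace, IntensityTrace) else trace, dtype=float)
    n = y.size
    if n < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {n}")
    prefix = np.concatenate([[0.0], np.cumsum(y)])
    prefix2 = np.concatenate([[0.0], np.cumsum(y * y)])

    # Greedy binary segmentation down to (near) zero residual, recording
    # the path, then global BIC selects the change-point count.  The
    # lookahead matters for staircases: one split alone may gain little
    # while the full set fits exactly.
    segments = [(0, n)]
    total_sse = _sse(prefix, prefix2, 0, n)
    eps = max(1e-12 * max(total_sse, 1.0), 1e-300)
    path: list[tuple[int, float]] = []  # (cp, total_sse after adding it)
    k_max = min(n - 1, 30)
    while len(path) < k_max and total_sse > eps:
        best = None
        for si, (a, b) in enumerate(segments):
            res = _best_split(prefix, prefix2, a, b)
            if res is None:
                continue
            cp, new_seg_sse = res
            gain_sse = _sse(prefix, prefix2, a, b) - new_seg_sse
            if best is None or gain_sse > best[0]:
                best = (gain_sse, si, cp)
        if best is None or best[0] <= 0:
            break
        gain_sse, si, cp = best
        a, b = segments[si]
        segments[si] = (a, cp)
        segments.insert(si + 1, (cp, b))
        total_sse -= gain_sse
        path.append((cp, total_sse))

    def bic_at(k: int) -> float:
        sse_k = _sse(prefix, prefix2, 0, n) if k == 0 else path[k - 1][1]
        return n * np.log(max(sse_k, eps) / n) + k * penalty_per_cp * np.log(n)

    k_best = min(range(len(path) + 1), key=bic_at)
    cps = sorted(cp for cp, _ in path[:k_best])
    total_sse = _sse(prefix, prefix2, 0, n) if k_best == 0 else path[k_best - 1][1]
    bounds = [0] + cps + [n]
    levels = [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    sigma2 = max(total_sse / n, eps)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    bic = -2 * ll + (len(cps) * penalty_per_cp + 2) * np.log(n)
    return StepModel(change_points=cps, levels=levels, log_likelihood=float(ll), bic=float(bic))


@dataclass
class Calibration:
    unit_step_intensity: float  # mu
    second_mean: float  # constrained to 2*mu
    weights: tuple[float, float]
    r_squared: float
    single_gaussian_fallback: bool = False

    def __post_init__(self) -> None:
        if self.unit_step_intensity <= 0:
            raise ValueError("unit step intensity must be > 0")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")


def _fd_bins(x: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bin edges."""
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return np.linspace(x.min() - 1, x.max() + 1, 11)
    width = 2 * iqr / len(x) ** (1 / 3)
    n_bins = max(int(np.ceil((x.max() - x.min()) / width)), 5)
    return np.linspace(x.min(), x.max(), n_bins + 1)


def calibrate_unit(step_sizes: np.ndarray, min_steps: int = 30) -> Calibration:
    """Unit fluorophore intensity from a step-size histogram.

    Fits a two-Gaussian model with the second component's mean pinned at
    twice the first; if the fitted second weight is < 0.02 the fit falls
    back to a single Gaussian (flagged, not an error).
    """
    x = np.asarray(step_sizes, dtype=float)
    x = x[x > 0]
    if x.size < min_steps:
        raise ValueError(f"need >= {min_steps} positive step sizes, got {x.size}")
    edges = _fd_bins(x)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # double-bleach frames are rarer than singles, so the second
    # amplitude is parameterized as a fraction (<= 1) of the first; this
    # also removes a local optimum where the 2*mu component swallows the
    # main peak
    def double(c, a1, mu, sig, frac2):
        return a1 * np.exp(-0.5 * ((c - mu) / sig) ** 2) + frac2 * a1 * np.exp(
            -0.5 * ((c - 2 * mu) / (sig * np.sqrt(2))) ** 2
        )

    def single(c, a1, mu, sig):
        return a1 * np.exp(-0.5 * ((c - mu) / sig) ** 2)

    mu0 = float(np.median(x))
    sig0 = max(float(np.std(x)) / 2, 1e-6)
    a0 = float(counts.max())
    n_bins = centers.size

    popt_s, _ = curve_fit(
        single, centers, counts, p0=[a0, mu0, sig0],
        bounds=([0, 1e-9, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20_000,
    )
    sse_s = float(np.sum((counts - single(centers, *popt_s)) ** 2))

    try:
        popt_d, _ = curve_fit(
            double, centers, counts,
            p0=[a0, float(popt_s[1]), float(popt_s[2]), 0.25],
            bounds=([0, 1e-9, 1e-9, 0], [np.inf, np.inf, np.inf, 1.0]),
            maxfev=20_000,
        )
        sse_d = float(np.sum((counts - double(centers, *popt_d)) ** 2))
        # one extra parameter must pay its BIC cost
        double_wins = (
            sse_d < sse_s
            and n_bins * np.log(max(sse_d, 1e-300) / max(sse_s, 1e-300)) + np.log(n_bins) < 0
        )
    except RuntimeError:
        double_wins = False

    w2 = 0.0
    if double_wins:
        a1, mu, sig, frac2 = popt_d
        m1 = a1 * sig  # component masses: amplitude * width
        m2 = frac2 * a1 * sig * np.sqrt(2)
        w2 = float(m2 / (m1 + m2))
    fallback = not double_wins or w2 < 0.02
    if fallback:
        mu = float(popt_s[1])
        w2 = 0.0
        pred = single(centers, *popt_s)
    else:
        pred = double(centers, *popt_d)

    ss_res = float(np.sum((counts - pred) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Calibration(
        unit_step_intensity=float(mu),
        second_mean=float(2 * mu),
        weights=(1 - float(w2), float(w2)),
        r_squared=r2,
        single_gaussian_fallback=fallback,
    )


def count_protomers(cluster_intensity: float, calibration: Calibration) -> int:
    """round(intensity / mu), floored at 1 for a detected cluster."""
    if calibration.unit_step_intensity <= 0:
        raise ValueError("calibration unit must be > 0")
    return max(1, int(round(cluster_intensity / calibration.unit_step_intensity)))


@dataclass
class ClusterTrack:
    cluster_id: int
    protomer_counts: np.ndarray  # per occupied frame (0 = absent)
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.protomer_counts = np.asarray(self.protomer_counts, dtype=int)
        if np.any(self.protomer_counts < 0):
            raise ValueError("protomer counts must be >= 0")


def detect_growth(track: ClusterTrack) -> list[int]:
    """Frames at which the protomer count increases by >= 1 between
    consecutive occupied frames."""
    c = track.protomer_counts
    if c.size < 2:
        raise ValueError("need >= 2 frames")
    occupied = np.nonzero(c > 0)[0]
    events = []
    for a, b in zip(occupied[:-1], occupied[1:]):
        if b == a + 1 and c[b] > c[a]:
            events.append(int(b))
    return events


def growth_frequency(tracks: list[ClusterTrack]) -> float:
    """Fraction of clusters on one molecule with >= 1 growth event."""
    if not tracks:
        raise ValueError("no tracks given")
    growing = sum(1 for t in tracks if len(detect_growth(t)) > 0)
    return growing / len(tracks)
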