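"""Polymer mechanics: WLC and extensible-FJC models, force-extension
curve generation/fitting, gap-length estimation and unit conversion.

Conventions: extensions in micrometres, forces in pN, contour/persistence
lengths in nm unless noted.  kBT defaults to 4.11 pN*nm (25 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "KBT_PN_NM",
    "DS_RISE_NM_PER_BP",
    "SS_CONTOUR_NM_PER_NT",
    "NM_PER_NT_AT_IMAGING_FORCE",
    "ForceExtensionCurve",
    "PolymerFit",
    "FitNonConvergence",
    "wlc_force",
    "wlc_extension",
    "fjc_extension",
    "generate_fe_curve",
    "fit_polymer",
    "gap_length",
    "nm_rate_to_nt_rate",
]

KBT_PN_NM = 4.11  # 25 C
DS_RISE_NM_PER_BP = 0.34
SS_CONTOUR_NM_PER_NT = 0.56
DEFAULT_LP_NM = 50.0
DEFAULT_KUHN_NM = 1.5
DEFAULT_STRETCH_PN = 800.0

# Extension of ssDNA per nucleotide at the ~15 pN imaging force.  Fixed
# as the single constant consistent with all four printed nm/min <->
# nt/min growth-rate pairs (ratio ~= 2.155 nt/nm).
NM_PER_NT_AT_IMAGING_FORCE = 0.464


class FitNonConvergence(RuntimeError):
    """Raised when a least-squares polymer fit fails to converge."""


@dataclass
class ForceExtensionCurve:
    extension_um: np.ndarray
    force_pN: np.ndarray
    construct: str = ""
    ds_bp: int | None = None  # ground truth when generated
    ss_nt: int | None = None

    def __post_init__(self) -> None:
        self.extension_um = np.asarray(self.extension_um, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.extension_um.shape != self.force_pN.shape:
            raise ValueError("extension and force arrays must have equal length")
        if np.any(self.extension_um <= 0):
            raise ValueError("extensions must be > 0")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = [f"# construct: {self.construct}"]
        if self.ds_bp is not None:
            header.append(f"# ds_bp: {self.ds_bp}")
        if self.ss_nt is not None:
            header.append(f"# ss_nt: {self.ss_nt}")
        lines = header + ["extension_um,force_pN"]
        lines += [f"{x:.9g},{f:.9g}" for x, f in zip(self.extension_um, self.force_pN)]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForceExtensionCurve":
        path = Path(path)
        meta: dict[str, str] = {}
        xs, fs = [], []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("extension_um"):
                x, f = line.split(",")
                xs.append(float(x))
                fs.append(float(f))
        return cls(
            extension_um=np.array(xs),
            force_pN=np.array(fs),
            construct=meta.get("construct", ""),
            ds_bp=int(meta["ds_bp"]) if "ds_bp" in meta else None,
            ss_nt=int(meta["ss_nt"]) if "ss_nt" in meta else None,
        )


@dataclass
class PolymerFit:
    model: Literal["WLC", "FJC", "series-mixture"]
    contour_length_um: float
    persistence_length_nm: float
    stretch_modulus_pN: float | None = None
    ss_contour_length_um: float | None = None  # series model only
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.contour_length_um <= 0:
            raise ValueError("contour length must be > 0")
        if self.persistence_length_nm <= 0:
            raise ValueError("persistence length must be > 0")

    @property
    def contour_length_bp(self) -> float:
        """Contour length expressed as dsDNA bp (0.34 nm rise)."""
        return self.contour_length_um * 1000.0 / DS_RISE_NM_PER_BP

    @property
    def ss_nt(self) -> float | None:
        if self.ss_contour_length_um is None:
            return None
        return self.ss_contour_length_um * 1000.0 / SS_CONTOUR_NM_PER_NT


def wlc_force(
    extension_um: float | np.ndarray,
    contour_length_um: float,
    persistence_length_nm: float = DEFAULT_LP_NM,
    kbt_pn_nm: float = KBT_PN_NM,
) -> float | np.ndarray:
    """Marko-Siggia interpolation force for a worm-like chain.

    F = (kBT/Lp) * [1/(4(1-x/Lc)^2) - 1/4 + x/Lc], valid for
    0 <= x < Lc.
    """
    x = np.asarray(extension_um, dtype=float)
    if np.any(x < 0) or np.any(x >= contour_length_um):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    r = x / contour_length_um
    f = (kbt_pn_nm / persistence_length_nm) * (0.25 / (1 - r) ** 2 - 0.25 + r)
    return float(f) if np.isscalar(extension_um) else f


def wlc_extension(
    force_pN: float | np.ndarray,
    contour_length_um: float,
    persistence_length_nm: float = DEFAULT_LP_NM,
    kbt_pn_nm: float = KBT_PN_NM,
) -> float | np.ndarray:
    """Numerical inverse of :func:`wlc_force` (bisection per point)."""
    def solve(f: float) -> float:
        if f <= 0:
            return 0.0
        hi = contour_length_um * (1 - 1e-9)
        return brentq(
            lambda x: wlc_force(x, contour_length_um, persistence_length_nm, kbt_pn_nm) - f,
            0.0,
            hi,
            xtol=1e-12,
        )

    if np.isscalar(force_pN):
        return solve(float(force_pN))
    return np.array([solve(float(f)) for f in np.asarray(force_pN, dtype=float)])


def fjc_extension(
    force_pN: float | np.ndarray,
    contour_length_um: float,
    kuhn_length_nm: float = DEFAULT_KUHN_NM,
    stretch_modulus_pN: float = DEFAULT_STRETCH_PN,
    kbt_pn_nm: float = KBT_PN_NM,
) -> float | np.ndarray:
    """Extensible freely-jointed chain extension.

    x = Lc * [coth(Fb/kBT) - kBT/(Fb)] * (1 + F/S)
    """
    if contour_length_um <= 0 or kuhn_length_nm <= 0 or stretch_modulus_pN <= 0:
        raise ValueError("contour, Kuhn length and stretch modulus must be > 0")
    f = np.asarray(force_pN, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be > 0")
    a = f * kuhn_length_nm / kbt_pn_nm
    langevin = 1.0 / np.tanh(a) - 1.0 / a
    x = contour_length_um * langevin * (1.0 + f / stretch_modulus_pN)
    return float(x) if np.isscalar(force_pN) else x


def _series_extension(
    force_pN: np.ndarray,
    ds_contour_um: float,
    ss_contour_um: float,
    persistence_length_nm: float = DEFAULT_LP_NM,
    kuhn_length_nm: float = DEFAULT_KUHN_NM,
    stretch_modulus_pN: float = DEFAULT_STRETCH_PN,
) -> np.ndarray:
    x = np.zeros_like(np.asarray(force_pN, dtype=float))
    if ds_contour_um > 0:
        x = x + wlc_extension(force_pN, ds_contour_um, persistence_length_nm)
    if ss_contour_um > 0:
        x = x + fjc_extension(force_pN, ss_contour_um, kuhn_length_nm, stretch_modulus_pN)
    return x


def generate_fe_curve(
    ds_bp: int,
    ss_nt: int,
    forces_pN: np.ndarray | None = None,
    persistence_length_nm: float = DEFAULT_LP_NM,
    kuhn_length_nm: float = DEFAULT_KUHN_NM,
    stretch_modulus_pN: float = DEFAULT_STRETCH_PN,
    noise_sigma_pN: float = 0.0,
    seed: int | None = None,
    construct: str = "",
) -> ForceExtensionCurve:
    """Series WLC(ds) + FJC(ss) force-extension curve, optionally noisy.

    At each force the total extension is the sum of the two segment
    extensions; Gaussian noise (``noise_sigma_pN``) is added to force.
    """
    if ds_bp + ss_nt <= 0:
        raise ValueError("ds_bp + ss_nt must be > 0")
    if forces_pN is None:
        forces_pN = np.linspace(0.25, 40.0, 160)
    forces_pN = np.asarray(forces_pN, dtype=float)
    ds_um = ds_bp * DS_RISE_NM_PER_BP / 1000.0
    ss_um = ss_nt * SS_CONTOUR_NM_PER_NT / 1000.0
    ext = _series_extension(
        forces_pN, ds_um, ss_um, persistence_length_nm, kuhn_length_nm, stretch_modulus_pN
    )
    force = forces_pN.copy()
    if noise_sigma_pN > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sigma_pN, size=force.shape)
    return ForceExtensionCurve(
        extension_um=ext, force_pN=force, construct=construct, ds_bp=ds_bp, ss_nt=ss_nt
    )


def fit_polymer(
    curve: ForceExtensionCurve,
    model: Literal["WLC", "FJC", "series-mixture"] = "WLC",
    force_window_pN: tuple[float, float] = (2.0, 30.0),
    fit_lp: bool = False,
    persistence_length_nm: float = DEFAULT_LP_NM,
    kuhn_length_nm: float = DEFAULT_KUHN_NM,
    stretch_modulus_pN: float = DEFAULT_STRETCH_PN,
) -> PolymerFit:
    """Least-squares fit of contour length(s) to a force-extension curve.

    Fits extension as a function of force inside ``force_window_pN``
    (default 2-30 pN, below the overstretching plateau).  For the WLC
    model Lp may optionally float; for the series model the dsDNA and
    ssDNA contour lengths are both free.
    """
    lo, hi = force_window_pN
    mask = (curve.force_pN >= lo) & (curve.force_pN <= hi)
    if mask.sum() < 10:
        raise ValueError(
            f"need >= 10 points in the {lo}-{hi} pN window, got {int(mask.sum())}"
        )
    f = curve.force_pN[mask]
    x = curve.extension_um[mask]
    x0 = float(np.max(x))

    try:
        if model == "WLC":
            if fit_lp:
                popt, _ = curve_fit(
                    lambda ff, lc, lp: wlc_extension(ff, lc, lp),
                    f, x, p0=[x0 * 1.05, persistence_length_nm],
                    bounds=([x0, 1.0], [10 * x0, 500.0]),
                )
                lc, lp = popt
            else:
                popt, _ = curve_fit(
                    lambda ff, lc: wlc_extension(ff, lc, persistence_length_nm),
                    f, x, p0=[x0 * 1.05], bounds=([x0], [10 * x0]),
                )
                lc, lp = popt[0], persistence_length_nm
            resid = x - wlc_extension(f, lc, lp)
            return PolymerFit("WLC", float(lc), float(lp),
                              residual_norm=float(np.linalg.norm(resid)))
        if model == "FJC":
            popt, _ = curve_fit(
                lambda ff, lc: fjc_extension(ff, lc, kuhn_length_nm, stretch_modulus_pN),
                f, x, p0=[x0], bounds=([x0 * 0.2], [10 * x0]),
            )
            lc = float(popt[0])
            resid = x - fjc_extension(f, lc, kuhn_length_nm, stretch_modulus_pN)
            return PolymerFit("FJC", lc, kuhn_length_nm / 2.0,
                              stretch_modulus_pN=stretch_modulus_pN,
                              residual_norm=float(np.linalg.norm(resid)))
        if model == "series-mixture":
            popt, _ = curve_fit(
                lambda ff, ds, ss: _series_extension(
                    ff, ds, ss, persistence_length_nm, kuhn_length_nm, stretch_modulus_pN
                ),
                f, x, p0=[x0 * 0.8, x0 * 0.2],
                bounds=([0.0, 0.0], [10 * x0, 10 * x0]),
            )
            ds_um, ss_um = float(popt[0]), float(popt[1])
            resid = x - _series_extension(
                f, ds_um, ss_um, persistence_length_nm, kuhn_length_nm, stretch_modulus_pN
            )
            return PolymerFit(
                "series-mixture",
                contour_length_um=ds_um + ss_um,
                persistence_length_nm=persistence_length_nm,
                stretch_modulus_pN=stretch_modulus_pN,
                ss_contour_length_um=ss_um,
                residual_norm=float(np.linalg.norm(resid)),
            )
    except RuntimeError as exc:  # curve_fit non-convergence
        raise FitNonConvergence(f"{model} fit did not converge: {exc}") from exc
    raise ValueError(f"unknown model {model!r}")


def gap_length(gapped_fit: PolymerFit, reference_ds_fit: PolymerFit) -> float:
    """ssDNA gap length (nt) from the contour-length increase of a gapped
    molecule over its fully-duplex reference.

    Replacing one bp of duplex (0.34 nm) with one nt of ssDNA contour
    (0.56 nm) raises the apparent contour length by 0.22 nm, so
    gap_nt = dLc / (0.56 - 0.34).
    """
    d_lc_nm = (gapped_fit.contour_length_um - reference_ds_fit.contour_length_um) * 1000.0
    gap_nt = d_lc_nm / (SS_CONTOUR_NM_PER_NT - DS_RISE_NM_PER_BP)
    if gap_nt < 0:
        raise ValueError(
            f"negative inferred gap ({gap_nt:.0f} nt): gapped contour is "
            "shorter than the duplex reference"
        )
    return gap_nt


def nm_rate_to_nt_rate(v_nm_per_min: float | np.ndarray) -> float | np.ndarray:
    """Convert a growth rate from nm/min to nt/min at the imaging force."""
    v = np.asarray(v_nm_per_min, dtype=float)
    if np.any(v < 0):
        raise ValueError("rate must be >= 0")
    out = v / NM_PER_NT_AT_IMAGING_FORCE
    return float(out) if np.isscalar(v_nm_per_min) else out
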