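"""File formats: kymographs as multi-page TIFF (+ JSON sidecar) or HDF5,
run configuration in YAML, and the end-to-end pipeline driver.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .sim_core import SimConfig, condition_preset, simulate_assembly
from .sim_render import Kymograph, RenderConfig, render_force, render_kymograph

__all__ = [
    "MissingMetadataError",
    "read_kymograph",
    "write_kymograph",
    "RunConfig",
    "run_pipeline",
]

CHANNEL_ORDER = ("blue", "green", "red")


class MissingMetadataError(ValueError):
    """A required calibration attribute is absent from a kymograph file."""


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write a kymograph as TIFF (+ `.json` sidecar) or HDF5 by suffix."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(kymo, path)
    elif path.suffix in (".tif", ".tiff"):
        _write_tiff(kymo, path)
    else:
        raise ValueError(f"unsupported kymograph suffix {path.suffix!r}")


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    if path.suffix in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unsupported kymograph suffix {path.suffix!r}")


def _write_tiff(kymo: Kymograph, path: Path) -> None:
    pages = np.stack([kymo.channels[c] for c in CHANNEL_ORDER if c in kymo.channels])
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {
        "channels": [c for c in CHANNEL_ORDER if c in kymo.channels],
        "pixel_size_nm": kymo.pixel_size_nm,
        "line_time_s": kymo.line_time_s,
        "orientation": kymo.orientation,
        "metadata": kymo.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_tiff(path: Path) -> Kymograph:
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise MissingMetadataError(
            f"kymograph sidecar {sidecar_path.name} not found; calibration "
            "metadata (pixel_size_nm, line_time_s, orientation) is required"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_size_nm", "line_time_s", "orientation"):
        if key not in meta:
            raise MissingMetadataError(f"sidecar is missing required attribute {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    channels = {name: np.asarray(pages[i], dtype=np.float32)
                for i, name in enumerate(meta["channels"])}
    return Kymograph(
        channels=channels,
        pixel_size_nm=meta["pixel_size_nm"],
        line_time_s=meta["line_time_s"],
        orientation=meta["orientation"],
        metadata=meta.get("metadata", {}),
    )


def _write_h5(kymo: Kymograph, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("channels")
        for name, arr in kymo.channels.items():
            grp.create_dataset(name, data=arr.astype(np.float32))
        h5.attrs["pixel_size_nm"] = kymo.pixel_size_nm
        h5.attrs["line_time_s"] = kymo.line_time_s
        h5.attrs["orientation"] = kymo.orientation
        h5.attrs["metadata_json"] = json.dumps(kymo.metadata)


def _read_h5(path: Path) -> Kymograph:
    with h5py.File(path, "r") as h5:
        for key in ("pixel_size_nm", "line_time_s", "orientation"):
            if key not in h5.attrs:
                raise MissingMetadataError(f"HDF5 file is missing required attribute {key!r}")
        channels = {name: np.asarray(ds, dtype=np.float32)
                    for name, ds in h5["channels"].items()}
        return Kymograph(
            channels=channels,
            pixel_size_nm=float(h5.attrs["pixel_size_nm"]),
            line_time_s=float(h5.attrs["line_time_s"]),
            orientation=str(h5.attrs["orientation"]),
            metadata=json.loads(h5.attrs.get("metadata_json", "{}")),
        )


# -- run configuration -------------------------------------------------------

_RUNCONFIG_KEYS = {"preset", "sim", "render", "seed", "output_dir", "stages", "n_frames"}


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML round-trippable)."""

    preset: str = "none"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    render: dict = field(default_factory=dict)  # RenderConfig overrides
    seed: int = 0
    output_dir: str = "filakit_out"
    stages: list[str] = field(default_factory=lambda: ["simulate", "render", "analyze"])
    n_frames: int | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> render -> analyze, writing CSV/JSON results.

    Every output carries the seed and a hash of the config; identical
    configs reproduce identical outputs.
    """
    from .kymo_analysis import (
        count_filaments_over_time,
        downsample_force,
        quantify_displacement,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    kymo = None
    if "simulate" in config.stages:
        sim_cfg = condition_preset(config.preset, seed=config.seed, **config.sim)
        log = simulate_assembly(sim_cfg)
        log.to_csv(out / "events.csv")
        results["n_events"] = len(log)
        if "render" in config.stages:
            rcfg = RenderConfig(**config.render)
            kymo = render_kymograph(log, rcfg, n_frames=config.n_frames, seed=config.seed)
            write_kymograph(kymo, out / "kymograph.h5")
            force = render_force(log, seed=config.seed)
            force_ds = downsample_force(force)
            np.savetxt(
                out / "force_3hz.csv",
                np.column_stack([force_ds.time_s, force_ds.force_pN]),
                delimiter=",", header="time_s,force_pN", comments="",
            )
    elif (out / "kymograph.h5").exists():
        kymo = read_kymograph(out / "kymograph.h5")

    if "analyze" in config.stages and kymo is not None:
        disp = quantify_displacement(kymo)
        results["displacement"] = {
            "rate_per_min": disp.rate_per_min,
            "half_time_min": disp.half_time_min,
            "baseline": disp.baseline,
        }
        if kymo.n_frames >= 25:
            nuc = count_filaments_over_time(kymo)
            results["nucleation"] = {
                "a_max": nuc.a_max,
                "rate_per_min": nuc.rate_per_min,
                "degenerate": nuc.degenerate,
            }
    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    return results
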