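"""Kinetic Monte Carlo simulation of recombinase filament assembly on ssDNA.

The lattice is a 1-D array of nucleotides; position 0 is the 5' end of the
ssDNA strand (0-based, half-open intervals).  Filaments nucleate as
monomers or dimers, grow by single-protomer addition at either end,
shrink by geometric bursts of protomers from uncapped ends, and may carry
a transient mediator cap on their 5'-proximal end that suppresses
dissociation there.  The simulation is an exact Gillespie (direct-method)
trajectory, so all waiting times are exponential by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Event",
    "EventLog",
    "simulate_assembly",
    "occupancy_timeseries",
    "simulate_dipping",
    "condition_preset",
    "PRESETS",
]

#: nt occluded per bound protomer
DEFAULT_FOOTPRINT_NT = 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one assembly simulation.

    Rates are per minute.  ``nucleation_rate_const_J`` has units of
    events per nt per min per nM**n, so the total nucleation propensity
    on a bare lattice is ``J * conc**n * lattice_length_nt``.
    """

    lattice_length_nt: int = 20_000
    rad51_conc: float = 500.0  # nM
    nucleation_rate_const_J: float = 3.0e-7
    nucleation_exponent_n: float = 1.6
    monomer_nucleation_fraction: float = 0.4
    footprint_nt: int = DEFAULT_FOOTPRINT_NT
    add_rate_5p: float = 27.0  # protomers / min / exposed end
    add_rate_3p: float = 27.0
    off_attempt_rate: float = 3.55  # burst initiations / min / uncapped end
    burst_mean_protomers: float = 4.0
    cap_on_rate: float = 0.0  # bindings / min / exposed 5' end
    cap_dwell_tau_s: float = 11.3
    cap_blocks_addition: bool = False
    rpa_suppression_factor: float = 1.0  # multiplies J (0.1 emulates RPA)
    duration_min: float = 10.0
    seed: int = 0
    #: pre-placed filaments as ((position_nt, protomers), ...); they are
    #: logged as nucleation events at t = 0
    initial_filaments: tuple = ()

    def __post_init__(self) -> None:
        rates = {
            "nucleation_rate_const_J": self.nucleation_rate_const_J,
            "add_rate_5p": self.add_rate_5p,
            "add_rate_3p": self.add_rate_3p,
            "off_attempt_rate": self.off_attempt_rate,
            "cap_on_rate": self.cap_on_rate,
            "rad51_conc": self.rad51_conc,
            "rpa_suppression_factor": self.rpa_suppression_factor,
            "duration_min": self.duration_min,
        }
        for name, value in rates.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if not (0 < self.nucleation_exponent_n <= 3):
            raise ValueError(
                f"nucleation_exponent_n must be in (0, 3], got {self.nucleation_exponent_n}"
            )
        if not (0 <= self.monomer_nucleation_fraction <= 1):
            raise ValueError("monomer_nucleation_fraction must be in [0, 1]")
        if self.footprint_nt < 1:
            raise ValueError("footprint_nt must be >= 1")
        if self.lattice_length_nt < self.footprint_nt:
            raise ValueError(
                f"lattice ({self.lattice_length_nt} nt) shorter than one "
                f"footprint ({self.footprint_nt} nt)"
            )
        if self.cap_dwell_tau_s <= 0 or not math.isfinite(self.cap_dwell_tau_s):
            raise ValueError("cap_dwell_tau_s must be finite and > 0")
        if self.burst_mean_protomers < 1:
            raise ValueError("burst_mean_protomers must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "initial_filaments" in d:
            d["initial_filaments"] = tuple(tuple(x) for x in d["initial_filaments"])
        return cls(**d)


EVENT_KINDS = ("nucleate", "add", "burst", "cap_bind", "cap_release")
ENDS = ("5p", "3p", "n/a")


@dataclass(frozen=True)
class Event:
    time_min: float
    kind: str  # one of EVENT_KINDS
    position_nt: int
    protomer_count: int
    end: str  # one of ENDS
    filament_id: int


@dataclass
class EventLog:
    """Time-ordered record of simulated lattice events."""

    events: list[Event]
    config: SimConfig
    seed: int

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.events],
            columns=["time_min", "kind", "position_nt", "protomer_count", "end", "filament_id"],
        )

    def bound_protomers(self) -> np.ndarray:
        """Running bound-protomer count after each event."""
        delta = np.zeros(len(self.events))
        for i, e in enumerate(self.events):
            if e.kind in ("nucleate", "add"):
                delta[i] = e.protomer_count
            elif e.kind == "burst":
                delta[i] = -e.protomer_count
        return np.cumsum(delta)

    def to_csv(self, path: str | Path) -> None:
        """Write one event per row plus a JSON config sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"config": self.config.to_dict(), "seed": self.seed}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        path = Path(path)
        # "n/a" is a literal end tag; round_trip parsing keeps times exact
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        events = [
            Event(
                time_min=float(r.time_min),
                kind=str(r.kind),
                position_nt=int(r.position_nt),
                protomer_count=int(r.protomer_count),
                end=str(r.end),
                filament_id=int(r.filament_id),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, config=SimConfig.from_dict(meta["config"]), seed=meta["seed"])


class _Filament:
    __slots__ = ("lo", "hi", "capped", "fid")

    def __init__(self, fid: int, lo: int, hi: int):
        self.fid = fid
        self.lo = lo  # 5'-proximal edge (inclusive), nt
        self.hi = hi  # 3'-proximal edge (exclusive), nt
        self.capped = False

    @property
    def protomers(self) -> int:
        return (self.hi - self.lo) // DEFAULT_FOOTPRINT_NT


def simulate_assembly(config: SimConfig) -> EventLog:
    """Run one exact-stochastic assembly trajectory.

    Returns an :class:`EventLog` whose events are strictly ordered in
    time.  Identical configs (including seed) give identical logs.
    """
    rng = np.random.default_rng(config.seed)
    fp = config.footprint_nt
    L = config.lattice_length_nt
    j_eff = (
        config.nucleation_rate_const_J
        * config.rpa_suppression_factor
        * config.rad51_conc**config.nucleation_exponent_n
    )
    cap_release_rate = 60.0 / config.cap_dwell_tau_s  # per min

    filaments: dict[int, _Filament] = {}
    events: list[Event] = []
    next_id = 0
    t = 0.0
    for pos, protomers in config.initial_filaments:
        pos, protomers = int(pos), int(protomers)
        if pos < 0 or pos + protomers * fp > L:
            raise ValueError(f"initial filament ({pos}, {protomers}) exceeds lattice")
        filaments[next_id] = _Filament(next_id, pos, pos + protomers * fp)
        events.append(Event(0.0, "nucleate", pos, protomers, "n/a", next_id))
        next_id += 1

    while True:
        # -- build propensities from the position-sorted filament order
        order = sorted(filaments.values(), key=lambda f: f.lo)
        gaps = []
        cursor = 0
        for f in order:
            if f.lo - cursor >= fp:
                gaps.append((cursor, f.lo))
            cursor = f.hi
        if L - cursor >= fp:
            gaps.append((cursor, L))
        # valid monomer start sites
        n_sites = sum(b - a - fp + 1 for a, b in gaps)
        a_nuc = j_eff * n_sites
        channels: list[tuple[str, object, float]] = []
        total = a_nuc
        if a_nuc > 0:
            channels.append(("nucleate", None, a_nuc))
        for i, f in enumerate(order):
            free_below = f.lo - fp >= 0 and (i == 0 or order[i - 1].hi <= f.lo - fp)
            free_above = f.hi + fp <= L and (
                i == len(order) - 1 or order[i + 1].lo >= f.hi + fp
            )
            block_5p_add = f.capped and config.cap_blocks_addition
            if config.add_rate_5p > 0 and not block_5p_add and free_below:
                channels.append(("add_5p", f, config.add_rate_5p))
                total += config.add_rate_5p
            if config.add_rate_3p > 0 and free_above:
                channels.append(("add_3p", f, config.add_rate_3p))
                total += config.add_rate_3p
            if config.off_attempt_rate > 0:
                if not f.capped:
                    channels.append(("burst_5p", f, config.off_attempt_rate))
                    total += config.off_attempt_rate
                channels.append(("burst_3p", f, config.off_attempt_rate))
                total += config.off_attempt_rate
            if config.cap_on_rate > 0 and not f.capped:
                channels.append(("cap_bind", f, config.cap_on_rate))
                total += config.cap_on_rate
            if f.capped:
                channels.append(("cap_release", f, cap_release_rate))
                total += cap_release_rate

        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= config.duration_min:
            break

        # -- pick a channel
        u = rng.uniform(0, total)
        acc = 0.0
        chosen = channels[-1]
        for ch in channels:
            acc += ch[2]
            if u < acc:
                chosen = ch
                break
        kind, f, _ = chosen

        if kind == "nucleate":
            # choose a monomer start site uniformly among valid sites
            site_idx = int(rng.integers(0, n_sites))
            for a, b in gaps:
                span = b - a - fp + 1
                if site_idx < span:
                    start = a + site_idx
                    gap_end = b
                    break
                site_idx -= span
            monomer = rng.uniform() < config.monomer_nucleation_fraction
            n_proto = 1 if monomer else 2
            if start + n_proto * fp > gap_end:  # dimer does not fit; degrade
                n_proto = 1
            fil = _Filament(next_id, start, start + n_proto * fp)
            filaments[next_id] = fil
            events.append(Event(t, "nucleate", start, n_proto, "n/a", next_id))
            next_id += 1
        elif kind == "add_5p":
            f.lo -= fp
            events.append(Event(t, "add", f.lo, 1, "5p", f.fid))
        elif kind == "add_3p":
            events.append(Event(t, "add", f.hi, 1, "3p", f.fid))
            f.hi += fp
        elif kind in ("burst_5p", "burst_3p"):
            size = int(rng.geometric(1.0 / config.burst_mean_protomers))
            size = min(size, f.protomers)
            end = "5p" if kind == "burst_5p" else "3p"
            if end == "5p":
                events.append(Event(t, "burst", f.lo, size, "5p", f.fid))
                f.lo += size * fp
            else:
                f.hi -= size * fp
                events.append(Event(t, "burst", f.hi, size, "3p", f.fid))
            if f.protomers == 0:
                del filaments[f.fid]
        elif kind == "cap_bind":
            f.capped = True
            events.append(Event(t, "cap_bind", f.lo, 0, "5p", f.fid))
        elif kind == "cap_release":
            f.capped = False
            events.append(Event(t, "cap_release", f.lo, 0, "5p", f.fid))

    return EventLog(events=events, config=config, seed=config.seed)


def replay_occupancy(
    events: Iterable[Event], t: float, footprint_nt: int = DEFAULT_FOOTPRINT_NT
) -> dict[int, tuple[int, int]]:
    """Replay events up to (and including) time ``t``; return live intervals."""
    fil: dict[int, tuple[int, int]] = {}
    for e in events:
        if e.time_min > t:
            break
        if e.kind == "nucleate":
            fil[e.filament_id] = (e.position_nt, e.position_nt + e.protomer_count * footprint_nt)
        elif e.kind == "add":
            lo, hi = fil[e.filament_id]
            if e.end == "5p":
                fil[e.filament_id] = (lo - footprint_nt, hi)
            else:
                fil[e.filament_id] = (lo, hi + footprint_nt)
        elif e.kind == "burst":
            lo, hi = fil[e.filament_id]
            d = e.protomer_count * footprint_nt
            if e.end == "5p":
                lo += d
            else:
                hi -= d
            if hi - lo <= 0:
                del fil[e.filament_id]
            else:
                fil[e.filament_id] = (lo, hi)
    return fil


def occupancy_timeseries(
    log: EventLog, times: Sequence[float]
) -> list[dict]:
    """Covered intervals and coverage fraction at each requested time.

    Returns one dict per time with keys ``time_min``, ``intervals``
    (list of disjoint ``(lo, hi)`` nt tuples) and ``coverage`` in [0, 1].
    """
    L = log.config.lattice_length_nt
    fp = log.config.footprint_nt
    out = []
    for t in times:
        fil = replay_occupancy(log.events, t, fp)
        intervals = sorted(fil.values())
        covered = sum(hi - lo for lo, hi in intervals)
        out.append({"time_min": float(t), "intervals": intervals, "coverage": covered / L})
    return out


@dataclass
class DippingCluster:
    """One cluster observed across dipping frames, with ground truth."""

    filament_id: int
    position_nt: int
    first_frame: int
    last_frame: int
    censored: bool
    protomers_first: int
    protomers_max: int
    nucleus_protomers: int  # 1 = monomer, 2 = dimer


def simulate_dipping(
    config: SimConfig,
    n_cycles: int,
    incubation_s: float,
    frame_interval_s: float = 30.0,
) -> pd.DataFrame:
    """Simulate repeated incubate-then-image cycles.

    The assembly runs continuously for ``n_cycles * incubation_s`` and is
    observed at frames separated by ``frame_interval_s``.  Returns a table
    of clusters with ground-truth protomer counts and dwell frames; a
    cluster present in the final frame is marked censored.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    total_s = n_cycles * incubation_s
    if total_s <= 0:
        return pd.DataFrame(
            columns=[
                "filament_id", "position_nt", "first_frame", "last_frame",
                "censored", "protomers_first", "protomers_max", "nucleus_protomers",
            ]
        )
    cfg = config.replace(duration_min=total_s / 60.0)
    log = simulate_assembly(cfg)
    n_frames = int(total_s // frame_interval_s) + 1
    frame_times_min = np.arange(n_frames) * frame_interval_s / 60.0

    nucleus_size = {
        e.filament_id: e.protomer_count for e in log.events if e.kind == "nucleate"
    }
    seen: dict[int, DippingCluster] = {}
    for fi, t in enumerate(frame_times_min):
        live = replay_occupancy(log.events, t, cfg.footprint_nt)
        for fid, (lo, hi) in live.items():
            protomers = (hi - lo) // cfg.footprint_nt
            if fid not in seen:
                seen[fid] = DippingCluster(
                    filament_id=fid,
                    position_nt=lo,
                    first_frame=fi,
                    last_frame=fi,
                    censored=False,
                    protomers_first=protomers,
                    protomers_max=protomers,
                    nucleus_protomers=nucleus_size[fid],
                )
            else:
                c = seen[fid]
                c.last_frame = fi
                c.protomers_max = max(c.protomers_max, protomers)
        # clusters can in principle disappear and reappear within one
        # frame interval; sampling at the frame cadence is the observable
    for c in seen.values():
        c.censored = c.last_frame == n_frames - 1
    rows = [dataclasses.asdict(c) for c in seen.values()]
    df = pd.DataFrame(
        rows,
        columns=[
            "filament_id", "position_nt", "first_frame", "last_frame",
            "censored", "protomers_first", "protomers_max", "nucleus_protomers",
        ],
    )
    return df.sort_values("first_frame").reset_index(drop=True)


def cluster_lifetimes(log: EventLog) -> pd.DataFrame:
    """Continuous birth/death times of every filament in the log.

    ``death_min`` is NaN for filaments still alive at the end of the
    simulated duration (right-censored).
    """
    birth: dict[int, float] = {}
    death: dict[int, float] = {}
    protomers: dict[int, int] = {}
    for e in log.events:
        if e.kind == "nucleate":
            birth[e.filament_id] = e.time_min
            protomers[e.filament_id] = e.protomer_count
        elif e.kind == "add":
            protomers[e.filament_id] += 1
        elif e.kind == "burst":
            protomers[e.filament_id] -= e.protomer_count
            if protomers[e.filament_id] <= 0:
                death[e.filament_id] = e.time_min
    return pd.DataFrame(
        {
            "filament_id": list(birth),
            "birth_min": [birth[f] for f in birth],
            "death_min": [death.get(f, float("nan")) for f in birth],
        }
    )


def protomer_counts_per_frame(
    log: EventLog, frame_times_min: Sequence[float]
) -> dict[int, np.ndarray]:
    """Per-filament protomer count sampled at each frame time (0 = absent)."""
    fids = {e.filament_id for e in log.events if e.kind == "nucleate"}
    counts = {fid: np.zeros(len(frame_times_min), dtype=int) for fid in fids}
    for fi, t in enumerate(frame_times_min):
        live = replay_occupancy(log.events, t, log.config.footprint_nt)
        for fid, (lo, hi) in live.items():
            counts[fid][fi] = (hi - lo) // log.config.footprint_nt
    return counts


# -- condition presets -------------------------------------------------------

_BASE = SimConfig()

PRESETS: dict[str, SimConfig] = {
    "none": _BASE,
    "BRC2": _BASE.replace(
        nucleation_rate_const_J=_BASE.nucleation_rate_const_J * 4,
        add_rate_5p=_BASE.add_rate_5p * 1.4,
        add_rate_3p=_BASE.add_rate_3p * 1.4,
    ),
    "RFS1RIP1_WT": _BASE.replace(
        nucleation_rate_const_J=_BASE.nucleation_rate_const_J * 1.5,
        cap_on_rate=50.0,
        cap_dwell_tau_s=11.3,
        monomer_nucleation_fraction=0.5,
    ),
    "K56A": _BASE.replace(
        cap_on_rate=50.0,
        cap_dwell_tau_s=11.3 * 20,
        cap_blocks_addition=True,
    ),
    "combined": _BASE.replace(
        nucleation_rate_const_J=_BASE.nucleation_rate_const_J * 6,
        add_rate_5p=_BASE.add_rate_5p * 1.4,
        add_rate_3p=_BASE.add_rate_3p * 1.4,
        cap_on_rate=50.0,
        cap_dwell_tau_s=11.3,
    ),
}


def condition_preset(name: str, **overrides) -> SimConfig:
    """Named mediator-condition preset; extra kwargs override fields."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return cfg.replace(**overrides) if overrides else cfg
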