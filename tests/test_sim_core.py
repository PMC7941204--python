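import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filakit.sim_core import (
    Event,
    EventLog,
    SimConfig,
    cluster_lifetimes,
    condition_preset,
    occupancy_timeseries,
    replay_occupancy,
    simulate_assembly,
    simulate_dipping,
)


def brute_force_coverage(log, t):
    """Independent replay oracle: apply events on an explicit lattice."""
    lattice = np.zeros(log.config.lattice_length_nt, dtype=bool)
    fp = log.config.footprint_nt
    fil = {}
    for e in log.events:
        if e.time_min > t:
            break
        if e.kind == "nucleate":
            fil[e.filament_id] = [e.position_nt, e.position_nt + e.protomer_count * fp]
        elif e.kind == "add":
            lo, hi = fil[e.filament_id]
            if e.end == "5p":
                fil[e.filament_id][0] = lo - fp
            else:
                fil[e.filament_id][1] = hi + fp
        elif e.kind == "burst":
            lo, hi = fil[e.filament_id]
            if e.end == "5p":
                fil[e.filament_id][0] = lo + e.protomer_count * fp
            else:
                fil[e.filament_id][1] = hi - e.protomer_count * fp
            if fil[e.filament_id][0] >= fil[e.filament_id][1]:
                del fil[e.filament_id]
    for lo, hi in fil.values():
        lattice[lo:hi] = True
    return lattice.sum() / lattice.size


class TestConfigValidation:
    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError, match="add_rate_5p"):
            SimConfig(add_rate_5p=-1.0)

    def test_rejects_nonfinite_rate(self):
        with pytest.raises(ValueError):
            SimConfig(nucleation_rate_const_J=float("nan"))

    def test_rejects_short_lattice(self):
        with pytest.raises(ValueError, match="footprint"):
            SimConfig(lattice_length_nt=2)

    def test_rejects_bad_exponent(self):
        with pytest.raises(ValueError):
            SimConfig(nucleation_exponent_n=3.5)

    def test_rejects_bad_monomer_fraction(self):
        with pytest.raises(ValueError):
            SimConfig(monomer_nucleation_fraction=1.5)


class TestSimulateAssembly:
    def test_zero_rates_empty_log(self):
        cfg = SimConfig(
            nucleation_rate_const_J=0.0, add_rate_5p=0.0, add_rate_3p=0.0,
            off_attempt_rate=0.0, duration_min=5.0,
        )
        log = simulate_assembly(cfg)
        assert len(log) == 0
        occ = occupancy_timeseries(log, [0.0, 2.5, 5.0])
        assert all(o["coverage"] == 0.0 for o in occ)

    def test_nucleation_count_matches_poisson_oracle(self, nucleation_only_config):
        # oracle: N ~ Poisson(J c^n L T); mean within 3 SE over 100 seeds
        cfg = nucleation_only_config
        expected = (
            cfg.nucleation_rate_const_J
            * cfg.rad51_conc**cfg.nucleation_exponent_n
            * cfg.lattice_length_nt
            * cfg.duration_min
        )
        counts = [len(simulate_assembly(cfg.replace(seed=s))) for s in range(100)]
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_seeded_nucleus_linear_growth_oracle(self):
        # off = 0, add rate g both ends: protomers(t) = n0 + Poisson(2 g t)
        g, t_end, n0 = 3.0, 2.0, 4
        final = []
        for s in range(100):
            cfg = SimConfig(
                lattice_length_nt=20_000, nucleation_rate_const_J=0.0,
                off_attempt_rate=0.0, add_rate_5p=g, add_rate_3p=g,
                duration_min=t_end, seed=s, initial_filaments=((10_000, n0),),
            )
            log = simulate_assembly(cfg)
            lo, hi = replay_occupancy(log.events, t_end)[0]
            final.append((hi - lo) // 3)
        expected = n0 + 2 * g * t_end
        se = np.sqrt(2 * g * t_end / 100)
        assert abs(np.mean(final) - expected) < 3 * se

    def test_capping_doubles_5p_edge_velocity(self):
        from filakit.mechanics import NM_PER_NT_AT_IMAGING_FORCE as c_nm

        def edge_v(cap_on):
            vs = []
            for s in range(40):
                cfg = SimConfig(
                    lattice_length_nt=20_000, nucleation_rate_const_J=0.0,
                    cap_on_rate=50.0 if cap_on else 0.0, duration_min=2.0,
                    seed=s, initial_filaments=((8_000, 60),),
                )
                log = simulate_assembly(cfg)
                a = replay_occupancy(log.events, 0.0)
                b = replay_occupancy(log.events, 2.0)
                if 0 in b:
                    vs.append((a[0][0] - b[0][0]) / 2.0 * c_nm)
            return np.mean(vs)

        ratio = edge_v(True) / edge_v(False)
        assert 1.6 < ratio < 2.5

    def test_determinism_bit_stable(self):
        cfg = SimConfig(lattice_length_nt=5_000, duration_min=1.0, seed=42)
        a = simulate_assembly(cfg)
        b = simulate_assembly(cfg)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_different_seeds_differ(self):
        cfg = SimConfig(lattice_length_nt=5_000, duration_min=1.0)
        a = simulate_assembly(cfg.replace(seed=1))
        b = simulate_assembly(cfg.replace(seed=2))
        assert not a.to_dataframe().equals(b.to_dataframe())

    def test_protomer_conservation_nonnegative(self, seeded_filament_log):
        bound = seeded_filament_log.bound_protomers()
        assert (bound >= 0).all()

    def test_event_times_nondecreasing(self, seeded_filament_log):
        times = [e.time_min for e in seeded_filament_log.events]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_permanent_cap_blocks_all_5p_bursts(self):
        cfg = SimConfig(
            lattice_length_nt=10_000, nucleation_rate_const_J=0.0,
            cap_on_rate=1e5, cap_dwell_tau_s=1e12, duration_min=3.0, seed=3,
            initial_filaments=((4_000, 400),),
        )
        log = simulate_assembly(cfg)
        bursts_5p = [e for e in log.events if e.kind == "burst" and e.end == "5p"]
        bursts_3p = [e for e in log.events if e.kind == "burst" and e.end == "3p"]
        assert len(bursts_5p) == 0
        assert len(bursts_3p) > 0

    def test_nucleation_scales_as_c_to_the_n(self):
        # log-log regression over c in {50..800} recovers n within 0.15
        concs = np.array([50.0, 100.0, 200.0, 400.0, 800.0])
        means = []
        for c in concs:
            counts = [
                len(simulate_assembly(SimConfig(
                    lattice_length_nt=20_000, rad51_conc=c, add_rate_5p=0.0,
                    add_rate_3p=0.0, off_attempt_rate=0.0, duration_min=0.5,
                    seed=s,
                )))
                for s in range(30)
            ]
            means.append(np.mean(counts))
        slope = np.polyfit(np.log(concs), np.log(means), 1)[0]
        assert abs(slope - 1.6) < 0.15

    def test_doubling_J_doubles_count(self, nucleation_only_config):
        cfg = nucleation_only_config
        c1 = [len(simulate_assembly(cfg.replace(seed=s))) for s in range(100)]
        cfg2 = cfg.replace(nucleation_rate_const_J=cfg.nucleation_rate_const_J * 2)
        c2 = [len(simulate_assembly(cfg2.replace(seed=s + 1000))) for s in range(100)]
        se = np.sqrt(np.var(c2) / 100 + 4 * np.var(c1) / 100)
        assert abs(np.mean(c2) - 2 * np.mean(c1)) < 3 * se

    def test_initial_filament_out_of_bounds(self):
        with pytest.raises(ValueError, match="lattice"):
            simulate_assembly(SimConfig(
                lattice_length_nt=100, initial_filaments=((99, 5),),
            ))


class TestOccupancy:
    def test_empty_log_zero_coverage(self):
        log = EventLog(events=[], config=SimConfig(), seed=0)
        occ = occupancy_timeseries(log, [0.0, 1.0, 5.0])
        assert all(o["coverage"] == 0.0 and o["intervals"] == [] for o in occ)

    def test_hand_counted_interval(self):
        # nucleate(2 protomers) + 4 adds = 6 protomers x 3 nt = 18 nt
        events = [
            Event(0.1, "nucleate", 300, 2, "n/a", 0),
            Event(0.2, "add", 297, 1, "5p", 0),
            Event(0.3, "add", 306, 1, "3p", 0),
            Event(0.4, "add", 294, 1, "5p", 0),
            Event(0.5, "add", 309, 1, "3p", 0),
        ]
        log = EventLog(events=events, config=SimConfig(lattice_length_nt=1000), seed=0)
        occ = occupancy_timeseries(log, [1.0])[0]
        assert occ["intervals"] == [(294, 312)]
        assert occ["coverage"] == pytest.approx(18 / 1000)

    def test_replay_matches_brute_force(self, seeded_filament_log):
        for t in [0.5, 1.7, 3.3, 5.0]:
            occ = occupancy_timeseries(seeded_filament_log, [t])[0]
            assert occ["coverage"] == pytest.approx(
                brute_force_coverage(seeded_filament_log, t)
            )

    def test_intervals_disjoint(self, seeded_filament_log):
        occ = occupancy_timeseries(seeded_filament_log, [2.0])[0]
        ivs = occ["intervals"]
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))


class TestDipping:
    def test_zero_incubation_no_clusters(self):
        df = simulate_dipping(SimConfig(), n_cycles=3, incubation_s=0.0)
        assert len(df) == 0

    def test_immortal_clusters_all_censored(self):
        cfg = SimConfig(
            lattice_length_nt=20_000, rad51_conc=300.0, add_rate_5p=0.0,
            add_rate_3p=0.0, off_attempt_rate=0.0, seed=5,
        )
        df = simulate_dipping(cfg, n_cycles=4, incubation_s=60.0)
        assert len(df) > 0
        assert df.censored.all()
        assert (df.last_frame == df.last_frame.max()).all()

    def test_dwell_distribution_ks_oracle(self):
        # monomer-only clusters die at rate 2*off; continuous lifetimes
        # of clusters born early are Exp(1/(2*off))
        from scipy import stats

        off = 1.0
        lifetimes = []
        for s in range(3):
            cfg = SimConfig(
                lattice_length_nt=30_000, rad51_conc=200.0,
                monomer_nucleation_fraction=1.0, add_rate_5p=0.0,
                add_rate_3p=0.0, off_attempt_rate=off, duration_min=20.0, seed=s,
            )
            log = simulate_assembly(cfg)
            df = cluster_lifetimes(log)
            early = df[df.birth_min < 10.0]
            lifetimes += list((early.death_min - early.birth_min).dropna())
        assert len(lifetimes) >= 500
        res = stats.kstest(np.array(lifetimes), "expon", args=(0, 1 / (2 * off)))
        assert res.pvalue > 0.01

    def test_cluster_ground_truth_columns(self):
        cfg = SimConfig(lattice_length_nt=20_000, rad51_conc=400.0, seed=9,
                        add_rate_5p=0.0, add_rate_3p=0.0, off_attempt_rate=0.0)
        df = simulate_dipping(cfg, 1, 60.0)
        assert set(df.nucleus_protomers) <= {1, 2}
        assert (df.protomers_first >= 1).all()


class TestEventLogSerialization:
    def test_csv_round_trip(self, seeded_filament_log, tmp_path):
        path = tmp_path / "events.csv"
        seeded_filament_log.to_csv(path)
        back = EventLog.from_csv(path)
        assert back.to_dataframe().equals(seeded_filament_log.to_dataframe())
        assert back.config == seeded_filament_log.config
        assert back.seed == seeded_filament_log.seed

    def test_empty_log_round_trip(self, tmp_path):
        log = EventLog(events=[], config=SimConfig(), seed=3)
        log.to_csv(tmp_path / "e.csv")
        back = EventLog.from_csv(tmp_path / "e.csv")
        assert len(back) == 0
        assert back.config == log.config


class TestPresets:
    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError, match="unknown preset"):
            condition_preset("nope")

    @pytest.mark.parametrize("name", ["none", "BRC2", "RFS1RIP1_WT", "K56A", "combined"])
    def test_presets_valid(self, name):
        cfg = condition_preset(name, seed=1)
        assert isinstance(cfg, SimConfig)
        assert cfg.seed == 1

    def test_k56a_blocks_addition(self):
        assert condition_preset("K56A").cap_blocks_addition
        assert not condition_preset("RFS1RIP1_WT").cap_blocks_addition


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_conservation_invariant_random_seeds(seed):
    cfg = SimConfig(lattice_length_nt=3_000, rad51_conc=300.0, duration_min=0.5, seed=seed)
    log = simulate_assembly(cfg)
    bound = log.bound_protomers()
    if len(bound):
        assert (bound >= 0).all()
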