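import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tssarna import (
    PolSimConfig,
    RhythmSchedule,
    length_histogram,
    modal_lengths,
    run_cell,
    scan_parameters,
    simulate,
    simulate_growth_curve,
    smooth_steady_state_rates,
    steady_state_rates,
)

from bruteforce_polsim import brute_force

SMALL_CONFIGS = [
    dict(L=60, dtau=4, pauses=((20, 11),), T=1200),
    dict(L=60, dtau=4, pauses=((20, 3),), T=1200),
    dict(L=60, dtau=7, pauses=((20, 7),), T=1200),
    dict(L=60, dtau=3, pauses=((10, 9), (30, 27), (50, 81)), T=2400),
    dict(L=60, dtau=5, pauses=(), T=800),
    dict(L=40, dtau=2, pauses=((2, 15),), T=900),
    dict(L=60, dtau=4, pauses=((20, 11),), T=1200, v=2),
]


class TestAgainstBruteForce:
    @pytest.mark.parametrize("kw", SMALL_CONFIGS)
    def test_event_log_equivalence(self, kw):
        """The array stepper and the naive object-based simulator agree on
        every census quantity, whole run."""
        cfg = PolSimConfig(burn_in=0, **kw)
        res = simulate(cfg)
        log, alive = brute_force(kw["L"], kw["dtau"], kw.get("pauses", ()), kw["T"],
                                 v=kw.get("v", 1))
        assert res.initiations == log.count("initiation")
        assert res.blocked_initiations == log.count("blocked")
        assert res.full_length_count == log.count("full")
        brute_lengths = np.bincount(log.lengths("truncated"), minlength=kw["L"] + 1)
        for length, count in res.truncated_counts.items():
            assert brute_lengths[length] == count
        assert sum(res.truncated_counts.values()) == log.count("truncated")
        assert res.in_progress == len(alive)

    def test_closed_form_validated_by_brute_force(self):
        """The quantized steady-state rates match brute-force event counts
        over whole cycles, for commensurate and incommensurate settings."""
        for dtau, dt in [(4, 12), (4, 11), (7, 7), (5, 23), (3, 100)]:
            L, pause = 50, 20
            full_rate, trunc = steady_state_rates(dtau, [(pause, dt)])
            cycle = round(1 / full_rate)
            t0 = 20 * max(dtau, dt)  # past the transient
            T = t0 + 40 * cycle
            log, _ = brute_force(L, dtau, [(pause, dt)], T)
            window = T - t0
            assert log.count("full", t_min=t0) == pytest.approx(full_rate * window, abs=1)
            assert log.count("truncated", t_min=t0) == pytest.approx(
                sum(trunc.values()) * window, abs=1
            )
            assert set(log.lengths("truncated")) <= {pause - 1}


class TestSteadyState:
    def test_no_pause_free_flow(self):
        cfg = PolSimConfig(L=100, dtau=7, T=8000, burn_in=1000)
        res = simulate(cfg)
        assert res.truncated_total == 0
        assert res.full_length_rate == pytest.approx(1 / 7, rel=0.01)

    def test_first_release_at_gene_transit_time(self):
        log, _ = brute_force(100, 7, (), 200)
        assert min(t for t, k, _ in log.events if k == "full") == 100

    def test_pause_shorter_than_initiation_interval_never_truncates(self):
        cfg = PolSimConfig(L=100, dtau=4, pauses=((36, 3),), T=8000, burn_in=1000)
        res = simulate(cfg)
        assert res.truncated_total == 0
        assert res.full_length_rate == pytest.approx(1 / 4, rel=0.01)

    def test_single_pause_quantized_rates(self):
        # dt=250 with dtau=4 locks the pause-entry cycle to 252
        res = run_cell(4, 250, L=2000, pause_pos=36, cycles=300)
        assert res.full_length_rate == pytest.approx(1 / 252, rel=0.005)
        assert res.truncated_rate == pytest.approx(62 / 252, rel=0.005)
        assert set(res.truncated_counts_steady) == {35}

    @given(
        st.integers(2, 12),
        st.integers(1, 40),
        st.booleans(),
        st.integers(1, 30),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_quantized_closed_form_holds_for_arbitrary_configs(self, dtau, dt_raw, slow, k):
        """Simulated rates converge to 1/(dtau*ceil(dt/dtau)) and its
        truncated complement for arbitrary (dtau, dt)."""
        dt = dt_raw + (dtau * k if slow else 0)
        L, pause = 120, 30
        full_rate, trunc = steady_state_rates(dtau, [(pause, dt)])
        cycle = round(1 / full_rate)
        burn_in = 20 * max(dtau, dt) + 2 * L
        T = burn_in + 300 * cycle
        res = simulate(PolSimConfig(L=L, dtau=dtau, pauses=((pause, dt),), T=T, burn_in=burn_in))
        assert res.full_length_rate == pytest.approx(full_rate, rel=0.01)
        assert res.truncated_rate == pytest.approx(sum(trunc.values()), rel=0.01, abs=1e-9)


class TestConservation:
    @given(
        st.integers(1, 9),
        st.lists(st.tuples(st.integers(2, 50), st.integers(0, 40)), max_size=3),
        st.integers(100, 1500),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_initiations_fully_accounted(self, dtau, raw_pauses, T):
        pauses = []
        seen = set()
        for pos, dt in sorted(raw_pauses):
            if pos not in seen:
                pauses.append((pos, dt))
                seen.add(pos)
        cfg = PolSimConfig(L=60, dtau=dtau, pauses=tuple(pauses), T=T, burn_in=0)
        res = simulate(cfg)
        assert (
            res.initiations
            == res.full_length_count
            + res.truncated_total
            + res.blocked_initiations
            + res.in_progress
        )

    def test_determinism(self):
        cfg = PolSimConfig(L=80, dtau=5, pauses=((30, 17),), T=4000)
        a, b = simulate(cfg), simulate(cfg)
        assert a.truncated_counts == b.truncated_counts
        assert a.full_length_count == b.full_length_count


class TestLengthHistogram:
    def test_multi_pause_band_pattern(self):
        """Pauses at 27/63/91/107 with increasing stall times yield truncated
        modes exactly one bp behind each pause."""
        pauses = ((27, 50), (63, 150), (91, 400), (107, 1000))
        cfg = PolSimConfig(L=2000, dtau=4, pauses=pauses, T=60_000, burn_in=14_000)
        res = simulate(cfg)
        hist = length_histogram(res)
        assert modal_lengths(hist) == [26, 62, 90, 106]
        assert set(hist) == {26, 62, 90, 106}
        full_rate, trunc = steady_state_rates(4, pauses)
        window = cfg.T - cfg.effective_burn_in
        for length, rate in trunc.items():
            assert hist[length] == pytest.approx(rate * window, rel=0.05)

    def test_single_pause_single_band(self):
        cfg = PolSimConfig(L=2000, dtau=4, pauses=((73, 250),), T=30_000)
        hist = length_histogram(simulate(cfg))
        assert modal_lengths(hist) == [72]
        assert set(hist) == {72}

    def test_no_pause_empty_histogram(self):
        cfg = PolSimConfig(L=200, dtau=5, T=4000)
        assert length_histogram(simulate(cfg)) == {}


class TestScanAndRhythm:
    def test_cell_against_itself_is_unit_fold(self):
        df = scan_parameters([4], [40], L=300, pause_pos=36, ref=(4, 40), cycles=100)
        assert df.log2_tssarna_fold.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert df.log2_cognate_fold.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_constant_schedule_gives_flat_profiles(self):
        schedule = RhythmSchedule(points=(((5, ((36, 40),)),) * 4), ref_index=0)
        df = simulate_growth_curve(schedule, L=300, cycles=100)
        assert np.allclose(df.log2_tssarna, 0.0)
        assert np.allclose(df.log2_cognate, 0.0)

    def test_varying_dtau_moves_tssarna_but_not_cognate(self):
        # full-length rate is pinned by the pause when dt >> dtau and the
        # dtau values divide dt evenly
        points = tuple((dtau, ((36, 240),)) for dtau in (4, 6, 8, 12))
        df = simulate_growth_curve(RhythmSchedule(points=points), L=300, cycles=150)
        assert np.allclose(df.log2_cognate, 0.0, atol=0.02)
        assert df.log2_tssarna.iloc[-1] < df.log2_tssarna.iloc[0] - 1.0

    def test_initiation_rate_conserved_when_dt_varies(self):
        points = tuple((6, ((36, dt),)) for dt in (42, 84, 168))
        total = []
        for dtau, pauses in points:
            full, trunc = steady_state_rates(dtau, pauses)
            total.append(full + sum(trunc.values()))
        assert np.allclose(total, 1 / 6)
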