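"""Stimulation builder: schedules, quantization, chunking, queue semantics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurostim import protocol as P
from neurostim import stim
from neurostim.asic import AsicState
from neurostim.errors import CapacityError, QuantizationError, SchedulingError

from conftest import SHORT


class TestSquareWave:
    def test_filter_test_wave_has_500_periods(self):
        """0.1 Hz for 5000 s gives 500 whole periods per channel."""
        cfg = stim.SquareWaveConfig(0.1, 5000.0, channels=(0,), dac7bit=83, dac4bit=3)
        sched = stim.build_square_wave(cfg)
        assert sched.n_events == 500
        shape = sched.shapes["square_period"]
        assert shape.duration == pytest.approx(10.0)

    def test_single_period_halves(self):
        cfg = stim.SquareWaveConfig(1.0, 1.0, dac7bit=10, dac4bit=15)
        sched = stim.build_square_wave(cfg)
        assert sched.n_events == 1
        shape = sched.shapes["square_period"]
        half = len(shape) // 2
        assert half / P.SAMPLE_RATE == pytest.approx(0.5)
        assert (shape.polarity[:half] == 1).all()
        assert (shape.polarity[half:] == 0).all()
        # time- and amplitude-symmetric: net charge is exactly zero
        assert shape.net_charge(dac10bit=48) == 0.0

    def test_92na_amplitude_quantizes_to_nearest_code(self):
        """The filter-test amplitude (92 nA at the gain-250 DAC pairing)
        maps to the code pair an exhaustive search finds."""
        d7, d4, rel_err = stim.nearest_dac_codes(92e-9, dac10bit=48)
        # independent brute-force oracle
        best, best_err = None, np.inf
        for a in range(128):
            for b in range(16):
                io = 48 * a * b / (1023 * 127 * 15) * 15e-6
                if abs(io - 92e-9) < best_err:
                    best, best_err = (a, b), abs(io - 92e-9)
        assert (d7, d4) == best
        assert rel_err == pytest.approx(best_err / 92e-9)
        assert rel_err < 1e-3

    def test_unrepresentable_amplitude_reports_nearest(self):
        with pytest.raises(QuantizationError, match="nearest code"):
            stim.nearest_dac_codes(1.0, dac10bit=48)  # 1 A is far out of range


class TestQuantizeWaveform:
    def test_zero_waveform_maps_to_zero_codes(self):
        shape = stim.quantize_waveform(np.zeros(100), full_scale=1.0)
        assert (shape.dac7bit == 0).all()

    def test_signed_code_space_has_256_combinations(self):
        """Full-scale ramp exercises the 7-bit magnitude x polarity space."""
        ramp = np.linspace(-1, 1, 100_001)
        shape = stim.quantize_waveform(ramp, full_scale=1.0)
        combos = set(zip(shape.dac7bit.tolist(), shape.polarity.tolist()))
        space = {(m, p) for m in range(128) for p in (0, 1)}
        assert combos <= space
        assert len(space) == 256
        # every nonzero magnitude appears with both polarities
        assert len(combos) == 255

    def test_ramp_quantization_is_monotone(self):
        ramp = np.linspace(-1, 1, 4001)
        shape = stim.quantize_waveform(ramp, full_scale=1.0)
        signed = shape.dac7bit.astype(int) * (2 * shape.polarity.astype(int) - 1)
        assert (np.diff(signed) >= 0).all()
        # brute-force check of round-to-nearest against the signed values
        expected = np.sign(ramp) * np.floor(np.abs(ramp) * 127 + 0.5)
        assert np.array_equal(signed, expected.astype(int))

    def test_clipping_warns_with_count(self):
        x = np.array([0.0, 0.5, 1.5, -2.0])
        with pytest.warns(UserWarning, match="2 samples clipped"):
            stim.quantize_waveform(x, full_scale=1.0)


@given(
    dac7=st.integers(1, 127),
    dac4=st.integers(1, 15),
    phase=st.integers(1, 40),
    dac10=st.integers(1, 1023),
)
def test_biphasic_shapes_are_charge_balanced(dac7, dac4, phase, dac10):
    """Equal-magnitude, equal-duration phases always sum to zero charge."""
    shape = stim.PulseShape.biphasic("p", dac7, dac4, phase)
    assert shape.net_charge(dac10) == 0.0


class TestScheduleValidation:
    def test_overlap_on_one_channel_rejected(self):
        shape = stim.PulseShape.biphasic("p", 10, 15, 5)
        sched = stim.StimulationSchedule(
            {"p": shape},
            [stim.StimEvent(0.0, 3, "p"), stim.StimEvent(0.0001, 3, "p")],
        )
        with pytest.raises(SchedulingError, match="channel 3"):
            sched.validate()

    def test_same_time_different_channels_allowed(self):
        shape = stim.PulseShape.biphasic("p", 10, 15, 5)
        sched = stim.StimulationSchedule(
            {"p": shape},
            [stim.StimEvent(0.0, 3, "p"), stim.StimEvent(0.0, 4, "p")],
        )
        sched.validate()


class TestBuildChunks:
    def test_pulse_round_trip_recovers_schedule(self):
        """Parsing built chunks reproduces every pulse start exactly."""
        shape = stim.PulseShape.biphasic("p", 20, 15, 5)
        events = [
            stim.StimEvent(0.0005, 0, "p"),
            stim.StimEvent(0.002, 70, "p"),    # second chip
            stim.StimEvent(0.00775, 0, "p"),
        ]
        sched = stim.StimulationSchedule({"p": shape}, events)
        chunks = stim.build_chunks(sched, chunk_seconds=SHORT)
        assert len(chunks) == 1
        pulses = stim.extract_pulses(chunks[0])
        expected = sorted((ev.start_period, ev.channel) for ev in events)
        assert pulses == expected

    def test_pulse_at_quarter_second_occupies_ten_periods(self):
        """A single 250 µs pulse at t = 0.25 s lands in chunk 0 and spans
        exactly 10 consecutive sampling periods."""
        shape = stim.PulseShape.biphasic("p", 30, 15, 5)  # 2 x 5 x 25 µs
        sched = stim.StimulationSchedule({"p": shape}, [stim.StimEvent(0.25, 2, "p")])
        chunks = stim.build_chunks(sched)
        assert len(chunks) == 1
        parsed = P.parse_chunk(chunks[0])
        active = np.flatnonzero(parsed.realtime[0].dac7bit[:, 2] > 0)
        assert np.array_equal(active, 10_000 + np.arange(10))

    def test_empty_schedule_builds_idle_realtime_chunks(self):
        chunks = stim.build_chunks(
            stim.StimulationSchedule(), n_chunks=2, chunk_seconds=SHORT
        )
        assert [c.sync_id for c in chunks] == [0, 1]
        for chunk in chunks:
            parsed = P.parse_chunk(chunk)
            stream = parsed.realtime[0]
            assert len(stream) == chunk.n_periods
            assert not stream.dac7bit.any()

    def test_setup_rides_in_first_chunk_only(self):
        state = AsicState(dac10bit=48, gain=250, stim_enable=True)
        chunks = stim.build_chunks(
            stim.StimulationSchedule(), {0: state}, n_chunks=2, chunk_seconds=SHORT
        )
        first = P.parse_chunk(chunks[0]).state_commands
        assert {c.register for c in first} == {
            "dac10bit", "hp_reg", "lp_reg", "gain", "stim_enable"
        }
        assert P.parse_chunk(chunks[1]).state_commands == []

    def test_trigger_raised_for_full_pulse_duration(self):
        shape = stim.PulseShape.biphasic("p", 20, 15, 4)
        sched = stim.StimulationSchedule(
            {"p": shape}, [stim.StimEvent(0.001, 5, "p")], trigger_line=2
        )
        chunk = stim.build_chunks(sched, chunk_seconds=SHORT)[0]
        trig = P.parse_chunk(chunk).triggers[:, 1]
        assert np.array_equal(np.flatnonzero(trig), 40 + np.arange(8))

    def test_pulse_spanning_chunk_boundary_continues(self):
        shape = stim.PulseShape.biphasic("p", 20, 15, 5)
        start = SHORT - 5 * 25e-6  # last 5 periods of chunk 0
        sched = stim.StimulationSchedule({"p": shape}, [stim.StimEvent(start, 0, "p")])
        chunks = stim.build_chunks(sched, n_chunks=2, chunk_seconds=SHORT)
        p0 = P.parse_chunk(chunks[0]).realtime[0]
        p1 = P.parse_chunk(chunks[1]).realtime[0]
        assert (p0.dac7bit[-5:, 0] > 0).all()
        assert (p1.dac7bit[:5, 0] > 0).all()
        assert not p1.dac7bit[5:, 0].any()
        # one pulse, attributed to the period of its onset in chunk 0
        pulses = stim.extract_pulses(chunks)
        assert pulses == [(int(round(start * P.SAMPLE_RATE)), 0)]

    def test_event_past_stream_end_rejected(self):
        shape = stim.PulseShape.biphasic("p", 20, 15, 5)
        sched = stim.StimulationSchedule({"p": shape}, [stim.StimEvent(1.0, 0, "p")])
        with pytest.raises(CapacityError):
            stim.build_chunks(sched, n_chunks=1, chunk_seconds=SHORT)


class TestStressProtocol:
    def test_pulse_count_conservation(self):
        """Pulses recovered from the chunks equal the scheduled pulses."""
        sched = stim.stress_protocol(
            pulses_per_second=20, channels=(0, 3, 6), duration=1.0, seed=7
        )
        chunks = stim.build_chunks(sched, chunk_seconds=SHORT, n_chunks=100)
        assert stim.count_pulses(chunks) == sched.n_events == 3 * 20

    def test_per_window_stratification(self):
        sched = stim.stress_protocol(pulses_per_second=40, channels=(0,), duration=1.0)
        starts = np.array([ev.start_period for ev in sched.events])
        assert np.count_nonzero(starts < 20_000) == 20
        assert np.count_nonzero(starts >= 20_000) == 20


class TestChunkQueue:
    def _chunk(self, words):
        return P.BitstreamChunk(words, SHORT)

    def test_keepalive_repeats_last_chunk_with_minus_one(self):
        words = P.pack_chunk([P.RealTimeDataCommand(9, 15, 1)], SHORT).words
        c0, c1 = self._chunk(words.copy()), self._chunk(words.copy())
        q = stim.ChunkQueue([c0, c1])
        assert q.next_chunk()[1] == 0
        assert q.next_chunk()[1] == 1
        for _ in range(3):
            repeat, sid = q.next_chunk()
            assert sid == -1 and repeat.sync_id == -1
            assert np.array_equal(repeat.words, c1.words)

    def test_refill_resumes_nonnegative_ids(self):
        words = P.pack_chunk([], SHORT).words
        q = stim.ChunkQueue([self._chunk(words)])
        q.next_chunk()
        assert q.next_chunk()[1] == -1
        q.push(self._chunk(words))
        assert q.next_chunk()[1] == 1

    def test_queue_holds_four_seconds(self):
        """8 standard 0.5 s chunks = 4 s; a 9th is refused."""
        words = np.zeros(P.chunk_word_count(0.5), dtype=np.uint16)
        q = stim.ChunkQueue()
        assert q.capacity == 8
        for _ in range(8):
            q.push(P.BitstreamChunk(words, 0.5))
        with pytest.raises(CapacityError):
            q.push(P.BitstreamChunk(words, 0.5))


class TestAlternatingSchedule:
    def test_two_arrays_sixteen_electrodes_revisit_64s(self):
        sched = stim.schedule_alternating(2, 16, 2.0, repetitions=2)
        assert stim.revisit_period(sched) == pytest.approx(64.0)
        # every electrode shares the same revisit period
        for ch in (0, 5, 64 + 15):
            assert stim.revisit_period(sched, ch) == pytest.approx(64.0)

    def test_degenerate_single_electrode(self):
        sched = stim.schedule_alternating(1, 1, 2.0, repetitions=2)
        assert stim.revisit_period(sched) == pytest.approx(2.0)

    def test_total_pulse_count(self):
        """10 repetitions x 8 amplitudes on 2 x 16 electrodes = 2560 pulses."""
        amps = [(d7, 15) for d7 in range(10, 90, 10)]
        sched = stim.schedule_alternating(2, 16, 2.0, amplitudes=amps, repetitions=10)
        assert sched.n_events == 2560

    def test_arrays_alternate_before_electrodes_advance(self):
        sched = stim.schedule_alternating(2, 3, 1.0)
        first_six = sorted(sched.events, key=lambda e: e.time)[:6]
        chips = [ev.channel // 64 for ev in first_six]
        assert chips == [0, 1, 0, 1, 0, 1]


class TestExperimentJson:
    def test_roundtrip_preserves_protocol(self, tmp_path):
        sched = stim.schedule_alternating(2, 4, 0.5, repetitions=2, trigger_line=3)
        setup = {0: AsicState(dac10bit=48, gain=250, stim_enable=True)}
        path = stim.save_experiment(tmp_path / "exp.json", sched, setup)
        sched2, setup2 = stim.load_experiment(path)
        assert sched2.trigger_line == 3
        assert sched2.events == sched.events
        assert set(sched2.shapes) == set(sched.shapes)
        for name in sched.shapes:
            for attr in ("dac7bit", "dac4bit", "polarity"):
                assert np.array_equal(
                    getattr(sched2.shapes[name], attr), getattr(sched.shapes[name], attr)
                )
        assert setup2[0].dac10bit == 48
        assert (setup2[0].gain == 250).all()
        assert setup2[0].stim_enable.all()

    def test_missing_section_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"version": 1, "shapes": {}}')
        with pytest.raises(ValueError, match="schedule"):
            stim.load_experiment(p)
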