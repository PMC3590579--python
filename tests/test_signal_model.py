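"""Recording I/O, protocol segmentation and result serialization."""

import json
import math

import numpy as np
import pytest

from pulsemei import (
    AmplitudeSeries,
    BeatSet,
    ProtocolSpec,
    PulseRecording,
    read_recording,
    read_result,
    segment_phases,
    write_result,
)
from pulsemei.entropy import MSECurve, mei
from pulsemei.signal_model import PhaseRanges, write_amplitude_csv


class TestProtocolSpec:
    def test_defaults_match_protocol(self):
        p = ProtocolSpec()
        assert (p.baseline_s, p.occlusion_s, p.hyperemia_s) == (300.0, 180.0, 540.0)
        assert p.total_s == 1020.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_s": 0},
            {"occlusion_s": -5},
            {"wrist_pressure_mmHg": 250.0},  # above occlusion pressure
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProtocolSpec(**kwargs)

    def test_from_yaml_file(self, tmp_path):
        cfg = tmp_path / "protocol.yaml"
        cfg.write_text("baseline_s: 60\nocclusion_s: 30\nhyperemia_s: 60\n")
        p = ProtocolSpec.from_file(cfg)
        assert p.total_s == 150.0

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "protocol.yaml"
        cfg.write_text("baseline_minutes: 5\n")
        with pytest.raises(ValueError, match="unknown"):
            ProtocolSpec.from_file(cfg)


class TestReadRecording:
    def test_single_column_full_length(self, tmp_path, rng):
        path = tmp_path / "rec.csv"
        np.savetxt(path, rng.standard_normal(510_000), fmt="%.5f")
        rec = read_recording(path, fs_hz=500.0)
        assert rec.duration_s == 1020.0
        assert rec.samples.size == 510_000

    def test_nan_row_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1.0\n2.0\nNaN\n4.0\n" * 20000)
        with pytest.raises(ValueError, match="row 3"):
            read_recording(path, fs_hz=500.0)

    def test_round_trip_preserves_samples(self, tmp_path, short_protocol, rng):
        samples = rng.standard_normal(int(short_protocol.total_s * 100))
        path = tmp_path / "rt.csv"
        np.savetxt(path, samples, fmt="%.17g")
        rec = read_recording(path, fs_hz=100.0, protocol=short_protocol)
        np.testing.assert_array_equal(rec.samples, samples)

    def test_time_column_checked_against_fs(self, tmp_path, short_protocol):
        n = int(short_protocol.total_s * 100)
        t = np.arange(n) / 100.0
        v = np.sin(t)
        path = tmp_path / "tv.csv"
        np.savetxt(path, np.column_stack([t, v]), delimiter=",")
        rec = read_recording(path, fs_hz=100.0, protocol=short_protocol)
        assert rec.samples.size == n
        with pytest.raises(ValueError, match="time column"):
            read_recording(path, fs_hz=500.0, protocol=short_protocol)

    def test_header_row_skipped(self, tmp_path, short_protocol):
        n = int(short_protocol.total_s * 100)
        path = tmp_path / "hdr.csv"
        path.write_text("value\n" + "\n".join("1.5" for _ in range(n)) + "\n")
        rec = read_recording(path, fs_hz=100.0, protocol=short_protocol)
        assert rec.samples.size == n

    def test_short_recording_rejected(self, tmp_path, short_protocol):
        path = tmp_path / "short.csv"
        np.savetxt(path, np.ones(100), fmt="%.1f")
        with pytest.raises(ValueError, match="too short"):
            read_recording(path, fs_hz=100.0, protocol=short_protocol)


class TestSegmentPhases:
    def test_default_protocol_at_500hz(self, rng):
        rec = PulseRecording(rng.standard_normal(510_000), 500.0)
        ph = segment_phases(rec)
        assert ph == PhaseRanges((0, 150_000), (150_000, 240_000), (240_000, 510_000))

    def test_custom_protocol(self, short_protocol, rng):
        rec = PulseRecording(
            rng.standard_normal(15_000), 100.0, protocol=short_protocol
        )
        ph = segment_phases(rec)
        assert ph == PhaseRanges((0, 6000), (6000, 9000), (9000, 15_000))

    @pytest.mark.parametrize("n", [5000, 12_000, 15_000, 15_050])
    def test_phases_partition_recording(self, short_protocol, rng, n):
        try:
            rec = PulseRecording(rng.standard_normal(n), 100.0, protocol=short_protocol)
            ph = segment_phases(rec)
        except ValueError:
            assert n < 0.99 * short_protocol.total_s * 100
            return
        assert ph.baseline[0] == 0
        assert ph.baseline[1] == ph.occlusion[0]
        assert ph.occlusion[1] == ph.hyperemia[0]
        assert ph.hyperemia[1] == rec.samples.size

    def test_truncated_recording_rejected(self, rng):
        rec = PulseRecording.__new__(PulseRecording)  # bypass length validation
        rec.samples = rng.standard_normal(100_000)
        rec.fs_hz = 500.0
        rec.protocol = ProtocolSpec()
        with pytest.raises(ValueError, match="shorter"):
            segment_phases(rec)


class TestDomainTypes:
    def test_beatset_rejects_footpoint_after_peak(self):
        with pytest.raises(ValueError):
            BeatSet(footpoint_idx=[10], peak_idx=[5], amplitude=[1.0])

    def test_beatset_rejects_nonpositive_amplitude(self):
        with pytest.raises(ValueError):
            BeatSet(footpoint_idx=[0, 20], peak_idx=[10, 30], amplitude=[1.0, 0.0])

    def test_amplitude_series_counts(self):
        s = AmplitudeSeries(
            values=np.ones(10), phase_split=4, beat_times_s=np.arange(10.0)
        )
        assert s.n_baseline == 3
        assert s.baseline_values.size == 3
        assert s.hyperemia_values.size == 7

    def test_amplitude_series_rejects_bad_split(self):
        with pytest.raises(ValueError):
            AmplitudeSeries(values=np.ones(5), phase_split=8, beat_times_s=np.arange(5.0))


class TestResultSerialization:
    def _mei_result(self, s_e):
        curve = MSECurve(
            tau=np.arange(1, 11),
            s_e=np.asarray(s_e, dtype=float),
            n_tau=(1000 // np.arange(1, 11)),
            flags=["ok" if math.isfinite(v) else "no_m_matches" for v in s_e],
        )
        return mei(curve)

    def test_mei_round_trip(self, tmp_path):
        res = self._mei_result(np.linspace(2.0, 1.0, 10))
        path = write_result(res, tmp_path / "mei.json", config={"m": 2}, seed=7)
        doc = read_result(path)
        assert doc["kind"] == "MEIResult"
        assert doc["provenance"]["seed"] == 7
        assert doc["payload"]["mei_ss"] == pytest.approx(res.mei_ss)
        np.testing.assert_allclose(doc["payload"]["curve"]["s_e"], res.curve.s_e)

    def test_nan_scale_serialized_as_null_with_flag(self, tmp_path):
        s_e = [1.0] * 9 + [math.nan]
        res = self._mei_result(s_e)
        path = write_result(res, tmp_path / "deg.json")
        raw = json.loads(path.read_text())
        assert raw["payload"]["curve"]["s_e"][9] is None
        assert raw["payload"]["curve"]["flags"][9] == "no_m_matches"
        assert raw["payload"]["mei_ls"] is None
        doc = read_result(path)
        assert math.isnan(doc["payload"]["curve"]["s_e"][9])

    def test_amplitude_csv_round_trip(self, tmp_path):
        import pandas as pd

        s = AmplitudeSeries(
            values=np.linspace(1, 2, 8), phase_split=5, beat_times_s=np.arange(8.0)
        )
        path = write_amplitude_csv(s, tmp_path / "amps.csv")
        df = pd.read_csv(path)
        np.testing.assert_allclose(df["amplitude"], s.values)
        assert list(df["phase"][:4]) == ["baseline"] * 4
        assert list(df["phase"][4:]) == ["hyperemia"] * 4
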