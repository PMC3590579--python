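"""Data model and file I/O for cuff-occlusion pulse recordings and derived series.

A recording follows a three-phase reactive-hyperemia protocol: a resting
baseline with the wrist cuff at low pressure, an upper-arm occlusion phase,
and a hyperemic phase after cuff release.  Downstream analysis works on the
per-beat amplitude series obtained by concatenating the baseline and
hyperemic beats (the occlusion segment carries no usable pulse waves).

Conventions: sample indexing is 0-based with half-open ranges; the beat index
``i`` used in prose and result documents is 1-based (``X_i``).  The
conversion between the two lives entirely in this module's types.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ProtocolSpec",
    "PulseRecording",
    "BeatSet",
    "AmplitudeSeries",
    "DetrendedSeries",
    "PhaseRanges",
    "read_recording",
    "segment_phases",
    "write_result",
    "read_result",
    "write_amplitude_csv",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and cuff pressures of the occlusion/reactive-hyperemia protocol.

    Defaults: 5 min baseline, 3 min occlusion, 9 min hyperemia; wrist cuff
    held at 40 mmHg throughout, upper-arm occlusion at 200 mmHg.
    """

    baseline_s: float = 300.0
    occlusion_s: float = 180.0
    hyperemia_s: float = 540.0
    wrist_pressure_mmHg: float = 40.0
    occlusion_pressure_mmHg: float = 200.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "occlusion_s", "hyperemia_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.occlusion_pressure_mmHg <= self.wrist_pressure_mmHg:
            raise ValueError(
                "occlusion pressure must exceed wrist cuff pressure "
                f"({self.occlusion_pressure_mmHg} <= {self.wrist_pressure_mmHg})"
            )

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.occlusion_s + self.hyperemia_s

    @classmethod
    def from_file(cls, path: str | Path) -> "ProtocolSpec":
        """Load protocol overrides from a YAML or JSON key-value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"protocol config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**data)


# Tolerance (seconds) for recordings slightly shorter/longer than the
# nominal protocol length; excess samples are truncated, never extrapolated.
LENGTH_TOLERANCE_S = 1.0


@dataclass
class PulseRecording:
    """A single-channel pressure-sensor time series with its protocol."""

    samples: np.ndarray
    fs_hz: float
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")
        nominal = self.protocol.total_s * self.fs_hz
        shortfall = nominal - self.samples.size
        if shortfall > LENGTH_TOLERANCE_S * self.fs_hz:
            raise ValueError(
                f"recording too short: {self.samples.size} samples, protocol "
                f"requires {nominal:.0f} (shortfall {shortfall / self.fs_hz:.2f} s)"
            )
        if -shortfall > LENGTH_TOLERANCE_S * self.fs_hz:
            # longer than protocol + tolerance: truncate to nominal length
            self.samples = self.samples[: int(round(nominal))]

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class BeatSet:
    """Detected beats of one phase: footpoint/peak sample indices and amplitudes."""

    footpoint_idx: np.ndarray
    peak_idx: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.footpoint_idx = np.asarray(self.footpoint_idx, dtype=int)
        self.peak_idx = np.asarray(self.peak_idx, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        n = self.peak_idx.size
        if not (self.footpoint_idx.size == n == self.amplitude.size):
            raise ValueError("footpoint/peak/amplitude lengths differ")
        if n:
            if np.any(self.footpoint_idx >= self.peak_idx):
                raise ValueError("each footpoint must precede its paired peak")
            if np.any(np.diff(self.peak_idx) <= 0) or np.any(np.diff(self.footpoint_idx) <= 0):
                raise ValueError("beat indices must be strictly increasing")
            if np.any(self.amplitude <= 0):
                raise ValueError("beat amplitudes must be positive")

    def __len__(self) -> int:
        return int(self.peak_idx.size)


@dataclass
class AmplitudeSeries:
    """Per-beat amplitudes X_i with baseline and hyperemic beats concatenated.

    ``phase_split`` is the 1-based index of the first hyperemic beat (the
    clinical convention: with 379 baseline beats the split is 380).
    ``beat_times_s`` are recording times of each beat's peak; occlusion-phase
    beats are absent by construction.
    """

    values: np.ndarray
    phase_split: int
    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        n = self.values.size
        if self.beat_times_s.size != n:
            raise ValueError("beat_times_s length must match values")
        if not 1 <= self.phase_split <= n + 1:
            raise ValueError(f"phase_split {self.phase_split} out of range for {n} beats")
        if n and (not np.all(np.isfinite(self.values)) or np.any(self.values <= 0)):
            raise ValueError("amplitudes must be finite and positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_baseline(self) -> int:
        return self.phase_split - 1

    @property
    def baseline_values(self) -> np.ndarray:
        return self.values[: self.n_baseline]

    @property
    def hyperemia_values(self) -> np.ndarray:
        return self.values[self.n_baseline:]


@dataclass
class DetrendedSeries:
    """Amplitude series with its slow nonstationary trend removed.

    ``values + trend`` reconstructs the source amplitudes exactly (to float
    round-off); the trend is the EMD residue plus optionally the slowest IMFs.
    """

    values: np.ndarray
    trend: np.ndarray
    source: AmplitudeSeries

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trend = np.asarray(self.trend, dtype=float)
        if self.values.size != len(self.source) or self.trend.size != self.values.size:
            raise ValueError("detrended/trend length must match source series")
        recon = self.values + self.trend
        scale = max(float(np.max(np.abs(self.source.values))), 1.0)
        if float(np.max(np.abs(recon - self.source.values))) > 1e-9 * scale:
            raise ValueError("values + trend does not reconstruct the source series")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PhaseRanges:
    """Half-open sample-index ranges of the three protocol phases."""

    baseline: tuple[int, int]
    occlusion: tuple[int, int]
    hyperemia: tuple[int, int]


def read_recording(
    path: str | Path,
    fs_hz: float = 500.0,
    protocol: Optional[ProtocolSpec] = None,
) -> PulseRecording:
    """Read a recording from CSV (one column of values, or time,value columns).

    A header row is optional.  When a time column is present its implied
    sampling rate must agree with ``fs_hz`` to within 1%.
    """
    path = Path(path)
    protocol = protocol or ProtocolSpec()
    try:
        import pandas as pd

        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"cannot parse CSV {path}: {exc}") from exc
    # drop a non-numeric header row if present
    first = df.iloc[0]
    if any(isinstance(v, str) and _not_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        data = df.astype(float).to_numpy()
    except (ValueError, TypeError):
        for i in range(len(df)):
            try:
                df.iloc[i].astype(float)
            except (ValueError, TypeError):
                raise ValueError(f"malformed row {i + 1} in {path}: {list(df.iloc[i])}")
        raise
    if data.shape[1] == 1:
        values = data[:, 0]
    elif data.shape[1] == 2:
        t, values = data[:, 0], data[:, 1]
        if t.size > 1:
            dt = np.median(np.diff(t))
            if dt <= 0 or abs(1.0 / dt - fs_hz) > 0.01 * fs_hz:
                raise ValueError(
                    f"time column implies fs={1.0 / dt if dt > 0 else math.nan:.3f} Hz, "
                    f"declared fs_hz={fs_hz}"
                )
    else:
        raise ValueError(f"expected 1 or 2 columns, got {data.shape[1]}")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite value at row {int(bad[0]) + 1} in {path}")
    return PulseRecording(samples=values, fs_hz=fs_hz, protocol=protocol)


def _not_number(s: str) -> bool:
    try:
        float(s)
        return False
    except ValueError:
        return True


def segment_phases(rec: PulseRecording) -> PhaseRanges:
    """Split a recording into baseline/occlusion/hyperemia sample ranges.

    Ranges are contiguous, non-overlapping, and together cover the recording
    exactly.  Raises if the recording is shorter than the protocol (beyond
    the declared ±1 s tolerance, in which case the final phase absorbs the
    truncation).
    """
    p = rec.protocol
    n = rec.samples.size
    b_end = int(round(p.baseline_s * rec.fs_hz))
    o_end = int(round((p.baseline_s + p.occlusion_s) * rec.fs_hz))
    if n < o_end:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s shorter than baseline+occlusion "
            f"({p.baseline_s + p.occlusion_s:.0f} s)"
        )
    return PhaseRanges(baseline=(0, b_end), occlusion=(b_end, o_end), hyperemia=(o_end, n))


# ---------------------------------------------------------------------------
# Result serialization


def _jsonify(obj: Any) -> Any:
    """Convert result objects to JSON-safe structures; NaN/inf become null + flag."""
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(_jsonify(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_result(result: Any, path: str | Path, *, config: Optional[dict] = None,
                 seed: Optional[int] = None) -> Path:
    """Serialize a result object (DIResult, MSECurve, MEIResult, or a dict of
    them) to JSON with provenance (config hash, seed).

    Non-finite entropy values are serialized as null; their per-scale flags
    travel alongside, so the document round-trips losslessly via
    :func:`read_result`.
    """
    path = Path(path)
    doc = {
        "kind": type(result).__name__,
        "payload": result.to_dict() if hasattr(result, "to_dict") else _jsonify(result),
        "provenance": {
            "config_hash": config_hash(config or {}),
            "seed": seed,
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, allow_nan=False) + "\n")
    return path


def read_result(path: str | Path) -> dict:
    """Read a result document written by :func:`write_result`.

    Returns the full document; ``doc["payload"]`` holds the result fields with
    null entropy values restored to NaN/inf according to the stored flags.
    """
    doc = json.loads(Path(path).read_text())
    payload = doc.get("payload", {})
    if isinstance(payload, dict) and "s_e" in payload and "flags" in payload:
        payload["s_e"] = _restore_flagged(payload["s_e"], payload["flags"])
    if isinstance(payload, dict) and isinstance(payload.get("curve"), dict):
        c = payload["curve"]
        if "s_e" in c and "flags" in c:
            c["s_e"] = _restore_flagged(c["s_e"], c["flags"])
    return doc


def _restore_flagged(values: list, flags: list) -> list:
    out = []
    for v, f in zip(values, flags):
        if v is None:
            out.append(math.inf if f == "no_m1_matches" else math.nan)
        else:
            out.append(v)
    return out


def write_amplitude_csv(series: AmplitudeSeries, path: str | Path) -> Path:
    """Export a beat-amplitude series as CSV (beat_index, time_s, amplitude, phase)."""
    import pandas as pd

    path = Path(path)
    n = len(series)
    phase = ["baseline"] * series.n_baseline + ["hyperemia"] * (n - series.n_baseline)
    pd.DataFrame(
        {
            "beat_index": np.arange(1, n + 1),
            "time_s": series.beat_times_s,
            "amplitude": series.values,
            "phase": phase,
        }
    ).to_csv(path, index=False)
    return path
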