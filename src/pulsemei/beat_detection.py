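"""Per-beat footpoint/peak detection and construction of the concatenated
baseline + hyperemia amplitude series.

The detector is standard tonometry/PPG practice and fully deterministic:
the phase segment is band-passed (0.5–10 Hz, zero-phase Butterworth), beats
are located as local maxima with prominence at least 0.3 × the rolling
median prominence and a refractory spacing of 60/max_hr seconds, peak
positions are refined on the raw signal, and each beat's footpoint is the
raw-signal minimum between the previous peak and the current one (for the
first beat, the minimum over the preceding 0.5 s).  The beat amplitude is
the vertical distance from the peak down to its onset footpoint, which makes
the measure insensitive to slow baseline drift.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sps

from .signal_model import AmplitudeSeries, BeatSet, PulseRecording

__all__ = ["detect_beats", "build_amplitude_series", "write_beats_csv"]

_BANDPASS_HZ = (0.5, 10.0)
_PROMINENCE_FRACTION = 0.3
_ROLLING_WINDOW_BEATS = 31  # centred window for the rolling prominence median


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    lo, hi = _BANDPASS_HZ
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _rolling_median(v: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        out[i] = np.median(v[max(0, i - half): i + half + 1])
    return out


def detect_beats(
    rec: PulseRecording,
    phase: tuple[int, int],
    min_hr_bpm: float = 40.0,
    max_hr_bpm: float = 150.0,
) -> BeatSet:
    """Detect beats within one phase of a recording.

    Returns a :class:`BeatSet` with sample indices relative to the whole
    recording.  Raises ``ValueError("no pulsatile activity")`` when fewer
    than 3 beats are found (flat or non-pulsatile segments).
    """
    if not 0 < min_hr_bpm < max_hr_bpm:
        raise ValueError(f"bad HR bounds: {min_hr_bpm}–{max_hr_bpm} bpm")
    start, stop = int(phase[0]), int(phase[1])
    seg = rec.samples[start:stop]
    fs = rec.fs_hz
    if seg.size < 3 * fs * 60.0 / min_hr_bpm:
        raise ValueError("phase too short: need at least 3 expected beat periods")
    if np.ptp(seg) == 0:
        raise ValueError("no pulsatile activity")

    filt = _bandpass(seg, fs)
    refractory = max(1, int(round(fs * 60.0 / max_hr_bpm)))
    cand, props = sps.find_peaks(filt, distance=refractory, prominence=1e-12)
    if cand.size < 3:
        raise ValueError("no pulsatile activity")
    prom = props["prominences"]
    thresh = _PROMINENCE_FRACTION * _rolling_median(prom, _ROLLING_WINDOW_BEATS)
    keep = prom >= thresh
    cand = cand[keep]
    if cand.size < 3:
        raise ValueError("no pulsatile activity")

    # refine each peak on the raw segment within ±100 ms
    half = int(round(0.1 * fs))
    peaks = np.empty(cand.size, dtype=int)
    for k, c in enumerate(cand):
        a, b = max(0, c - half), min(seg.size, c + half + 1)
        peaks[k] = a + int(np.argmax(seg[a:b]))
    peaks = np.unique(peaks)
    # enforce refractory spacing after refinement
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= refractory:
            kept.append(int(p))
        elif seg[p] > seg[kept[-1]]:
            kept[-1] = int(p)
    peaks = np.asarray(kept, dtype=int)
    if peaks.size < 3:
        raise ValueError("no pulsatile activity")

    # footpoint: raw minimum between the previous peak and this one
    lookback = int(round(0.5 * fs))
    feet = np.empty(peaks.size, dtype=int)
    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k else max(0, p - lookback)
        if lo >= p:
            lo = max(0, p - lookback)
        feet[k] = lo + int(np.argmin(seg[lo:p]))
    amp = seg[peaks] - seg[feet]
    good = amp > 0
    peaks, feet, amp = peaks[good], feet[good], amp[good]
    if peaks.size < 3:
        raise ValueError("no pulsatile activity")
    return BeatSet(
        footpoint_idx=feet + start,
        peak_idx=peaks + start,
        amplitude=amp,
    )


def build_amplitude_series(
    baseline_beats: BeatSet,
    hyperemia_beats: BeatSet,
    fs_hz: float = 500.0,
    n_beats: Optional[int] = None,
) -> AmplitudeSeries:
    """Concatenate baseline and hyperemic beat amplitudes into one series.

    The occlusion phase carries no beats, so the two phases are joined
    directly; ``phase_split`` is the 1-based index of the first hyperemic
    beat.  When ``n_beats`` is given the series is truncated to exactly that
    length by dropping beats from the end of each phase in proportion to the
    phase sizes (for strict fidelity to a fixed-length analysis).
    """
    if len(baseline_beats) == 0 or len(hyperemia_beats) == 0:
        raise ValueError("both phases must contain beats")
    nb, nh = len(baseline_beats), len(hyperemia_beats)
    if n_beats is not None:
        total = nb + nh
        if n_beats > total:
            raise ValueError(f"requested {n_beats} beats but only {total} detected")
        if n_beats < 2:
            raise ValueError("n_beats must be >= 2")
        nb_new = max(1, int(round(n_beats * nb / total)))
        nh_new = n_beats - nb_new
        if nh_new < 1:
            nb_new, nh_new = n_beats - 1, 1
        nb, nh = nb_new, nh_new
    values = np.concatenate([baseline_beats.amplitude[:nb], hyperemia_beats.amplitude[:nh]])
    times = np.concatenate(
        [baseline_beats.peak_idx[:nb], hyperemia_beats.peak_idx[:nh]]
    ) / fs_hz
    return AmplitudeSeries(values=values, phase_split=nb + 1, beat_times_s=times)


def write_beats_csv(baseline_beats: BeatSet, hyperemia_beats: BeatSet, path) -> None:
    """Export beat annotations as CSV: beat_index, footpoint_idx, peak_idx,
    amplitude, phase."""
    import pandas as pd

    frames = []
    for phase, beats in (("baseline", baseline_beats), ("hyperemia", hyperemia_beats)):
        frames.append(
            pd.DataFrame(
                {
                    "footpoint_idx": beats.footpoint_idx,
                    "peak_idx": beats.peak_idx,
                    "amplitude": beats.amplitude,
                    "phase": phase,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "beat_index", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
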