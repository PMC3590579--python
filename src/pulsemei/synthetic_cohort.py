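"""Seeded generator of protocol recordings emulating four subject archetypes.

The generator produces beat-amplitude series — and optionally full rendered
pressure waveforms with ground-truth manifests — for four archetypes spanning
the clinical spectrum from healthy young subjects to poorly controlled
diabetics.  Two properties distinguish the archetypes:

* hyperemic **gain** — the peak factor by which pulse amplitude rises after
  cuff release.  The amplitude envelope ramps up over ``rise_s`` seconds
  (vasodilation is not instantaneous, and the ramp keeps the envelope
  continuous across the deleted occlusion segment) and decays back with
  time constant ``rh_tau_s``.  Gains default to 2.0 / 1.65 / 1.6 / 1.33,
  anchored to typical dilatation-index group means near 200 %, 165 %, 162 %
  and 133 %.
* **complexity** — the spectral exponent β of the beat-to-beat amplitude
  fluctuations (power spectrum ∝ 1/f^β): 1 is fully 1/f-correlated, 0 is
  white.  Healthy regulation shows long-range-correlated fluctuations whose
  entropy persists across coarse-graining scales, while ageing and poor
  glycemic control whiten the fluctuations, lowering large-scale entropy.
  Defaults 0.85 / 0.55 / 0.35 / 0.15 are free modeling parameters,
  calibrated once so large-scale entropy orders the groups.

Everything is reproducible: one seed drives a ``numpy`` Generator, and
cohort subjects draw independent child seeds from a SeedSequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .signal_model import AmplitudeSeries, ProtocolSpec, PulseRecording

__all__ = [
    "ArchetypeParams",
    "GroundTruthManifest",
    "ARCHETYPES",
    "simulate_amplitude_series",
    "render_waveform",
    "simulate_cohort",
    "pink_noise",
    "powerlaw_noise",
]


@dataclass(frozen=True)
class ArchetypeParams:
    """Generator parameters for one subject archetype.

    hr_bpm: mean heart rate (71 bpm gives ~1000 beats over the 14 analyzed
    minutes); hr_cv: beat-interval coefficient of variation; base_amp:
    baseline mean amplitude (device units); gain: peak hyperemic amplitude
    gain; rise_s / rh_tau_s: hyperemic envelope rise time and decay
    constant; complexity: spectral exponent of the amplitude fluctuations
    (1 = 1/f, 0 = white); fluct_cv: fluctuation coefficient of variation
    relative to base_amp; snr_db: rendered sensor SNR.
    """

    hr_bpm: float = 71.0
    hr_cv: float = 0.04
    base_amp: float = 1.0
    gain: float = 2.0
    rise_s: float = 60.0
    rh_tau_s: float = 180.0
    complexity: float = 0.85
    fluct_cv: float = 0.12
    snr_db: float = 40.0
    group: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("hr_bpm", "base_amp", "gain", "rise_s", "rh_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hr_cv", "fluct_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.complexity <= 1.0:
            raise ValueError("complexity must lie in [0, 1]")


#: default archetypes for the four subject groups: healthy young, healthy
#: middle-aged/elderly, well-controlled diabetic, poorly controlled diabetic
ARCHETYPES: dict[int, ArchetypeParams] = {
    1: ArchetypeParams(gain=2.00, complexity=0.85, group=1),
    2: ArchetypeParams(gain=1.65, complexity=0.55, group=2),
    3: ArchetypeParams(gain=1.60, complexity=0.35, group=3),
    4: ArchetypeParams(gain=1.33, complexity=0.15, group=4),
}

#: metadata medians per group (age in years, HbA1c in %), used only as
#: subject annotations for cohort reporting
_GROUP_META = {
    1: {"age": 25.0, "hba1c": 5.5},
    2: {"age": 57.0, "hba1c": 5.7},
    3: {"age": 65.0, "hba1c": 6.8},
    4: {"age": 60.0, "hba1c": 9.9},
}


@dataclass
class GroundTruthManifest:
    """Ground truth emitted alongside a simulated recording."""

    beat_times: np.ndarray          # footpoint/onset time of each beat (s)
    peak_times: np.ndarray          # time of each beat's systolic peak (s)
    beat_amplitudes: np.ndarray
    phase: list                     # "baseline" | "hyperemia" per beat
    params: ArchetypeParams
    seed: int

    def to_dict(self) -> dict:
        return {
            "beat_times": np.asarray(self.beat_times, dtype=float).tolist(),
            "peak_times": np.asarray(self.peak_times, dtype=float).tolist(),
            "beat_amplitudes": np.asarray(self.beat_amplitudes, dtype=float).tolist(),
            "phase": list(self.phase),
            "params": asdict(self.params),
            "seed": int(self.seed),
        }


def powerlaw_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise with power spectrum ∝ 1/f^beta, by spectral
    synthesis (beta = 0 is white, beta = 1 is 1/f "pink" noise)."""
    if n < 2:
        return rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise (``powerlaw_noise`` at beta = 1)."""
    return powerlaw_noise(n, 1.0, rng)


def _fluctuations(n: int, params: ArchetypeParams, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean fluctuation stream with SD = fluct_cv, spectral exponent =
    complexity (1/f^beta noise interpolating white → pink)."""
    if params.fluct_cv == 0:
        return np.zeros(n)
    return params.fluct_cv * powerlaw_noise(n, params.complexity, rng)


def _beat_times(params: ArchetypeParams, protocol: ProtocolSpec,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Beat onset times for the baseline and hyperemic phases (occlusion skipped)."""
    mean_rr = 60.0 / params.hr_bpm
    min_rr = 0.4 * mean_rr

    def walk(start: float, stop: float) -> np.ndarray:
        times = []
        t = start + rng.uniform(0, mean_rr)
        while t < stop:
            times.append(t)
            rr = mean_rr * (1.0 + params.hr_cv * rng.standard_normal())
            t += max(rr, min_rr)
        return np.asarray(times)

    baseline = walk(0.0, protocol.baseline_s)
    h_start = protocol.baseline_s + protocol.occlusion_s
    hyperemia = walk(h_start, h_start + protocol.hyperemia_s)
    return baseline, hyperemia


def _envelope(t: np.ndarray, params: ArchetypeParams, release_s: float) -> np.ndarray:
    """Deterministic amplitude envelope: flat baseline, then a hyperemic bump
    (1 − e^{−t/rise}) · e^{−t/τ} after release, peak-normalized so the
    envelope tops out at base_amp × gain and returns toward baseline."""
    env = np.full(t.shape, params.base_amp)
    post = t >= release_s
    dt = t[post] - release_s
    s = (1.0 - np.exp(-dt / params.rise_s)) * np.exp(-dt / params.rh_tau_s)
    # peak of the rise-decay bump, in closed form
    t_peak = params.rise_s * np.log1p(params.rh_tau_s / params.rise_s)
    s_max = (1.0 - np.exp(-t_peak / params.rise_s)) * np.exp(-t_peak / params.rh_tau_s)
    env[post] = params.base_amp * (1.0 + (params.gain - 1.0) * s / s_max)
    return env


def simulate_amplitude_series(
    params: ArchetypeParams,
    n_beats: Optional[int] = None,
    seed: int = 0,
    protocol: Optional[ProtocolSpec] = None,
) -> tuple[AmplitudeSeries, GroundTruthManifest]:
    """Simulate the per-beat amplitude series X_i for one subject.

    X_i = envelope(t_i) + base_amp × fluct_i — a deterministic hyperemic
    envelope plus additive correlated fluctuations — with beats spanning the
    baseline and hyperemic phases (no occlusion beats).  ``n_beats``, if
    given (>= 20), truncates each phase proportionally to yield exactly that
    many beats.
    """
    protocol = protocol or ProtocolSpec()
    if n_beats is not None and n_beats < 20:
        raise ValueError("n_beats must be >= 20")
    rng = np.random.default_rng(seed)
    t_base, t_hyp = _beat_times(params, protocol, rng)
    if n_beats is not None:
        total = t_base.size + t_hyp.size
        if n_beats > total:
            raise ValueError(f"protocol yields only {total} beats, requested {n_beats}")
        nb = max(1, int(round(n_beats * t_base.size / total)))
        nh = n_beats - nb
        t_base, t_hyp = t_base[:nb], t_hyp[:nh]
    t = np.concatenate([t_base, t_hyp])
    release_s = protocol.baseline_s + protocol.occlusion_s
    env = _envelope(t, params, release_s)
    fluct = _fluctuations(t.size, params, rng)
    values = env + params.base_amp * fluct
    values = np.maximum(values, 0.05 * params.base_amp)  # amplitudes stay positive
    series = AmplitudeSeries(values=values, phase_split=t_base.size + 1, beat_times_s=t)
    manifest = GroundTruthManifest(
        beat_times=t,
        peak_times=t + _TEMPLATE_PEAK_S,
        beat_amplitudes=values,
        phase=["baseline"] * t_base.size + ["hyperemia"] * t_hyp.size,
        params=params,
        seed=int(seed),
    )
    return series, manifest


# --- waveform rendering ----------------------------------------------------

# asymmetric pulse template: fast systolic upstroke, slower decay with a
# dicrotic bump, as a sum of two Gaussian lobes; times in seconds from onset
_TEMPLATE_LEN_S = 0.80
_G1_T, _G1_W = 0.15, 0.055
_G2_T, _G2_W, _G2_A = 0.40, 0.12, 0.35
_MIN_RR_S = 0.35  # beats closer than this would overlap the template core


def _pulse_template(fs_hz: float) -> np.ndarray:
    t = np.arange(0.0, _TEMPLATE_LEN_S, 1.0 / fs_hz)
    p = np.exp(-((t - _G1_T) ** 2) / (2 * _G1_W**2)) + _G2_A * np.exp(
        -((t - _G2_T) ** 2) / (2 * _G2_W**2)
    )
    p -= p[0]
    np.maximum(p, 0.0, out=p)  # onset and tail both sit at zero
    return p / p.max()


_TEMPLATE_PEAK_S = float(
    np.argmax(_pulse_template(500.0)) / 500.0
)  # systolic peak offset from beat onset


def render_waveform(
    series: AmplitudeSeries,
    params: ArchetypeParams,
    fs_hz: float = 500.0,
    seed: int = 0,
    protocol: Optional[ProtocolSpec] = None,
) -> tuple[PulseRecording, GroundTruthManifest]:
    """Render a beat-amplitude series into a sampled pressure recording.

    Each beat is the asymmetric pulse template scaled to its amplitude and
    placed at its onset time; the occlusion phase is near-flat low-amplitude
    noise; white sensor noise is added at ``params.snr_db`` relative to the
    pulsatile signal power.
    """
    protocol = protocol or ProtocolSpec()
    t = series.beat_times_s
    if t.size > 1 and np.min(np.diff(t)) < _MIN_RR_S:
        raise ValueError(
            f"overlapping beats: minimum inter-beat interval "
            f"{np.min(np.diff(t)):.3f} s < {_MIN_RR_S} s"
        )
    rng = np.random.default_rng(seed)
    n = int(round(protocol.total_s * fs_hz))
    samples = np.zeros(n)
    template = _pulse_template(fs_hz)
    for onset, amp in zip(t, series.values):
        i0 = int(round(onset * fs_hz))
        i1 = min(n, i0 + template.size)
        if i0 >= n:
            continue
        samples[i0:i1] += amp * template[: i1 - i0]
    sig_rms = float(np.sqrt(np.mean(samples**2)))
    noise_sd = sig_rms / (10.0 ** (params.snr_db / 20.0))
    samples += noise_sd * rng.standard_normal(n)
    rec = PulseRecording(samples=samples, fs_hz=fs_hz, protocol=protocol,
                         meta={"group": params.group, "seed": int(seed)})
    manifest = GroundTruthManifest(
        beat_times=t,
        peak_times=t + _TEMPLATE_PEAK_S,
        beat_amplitudes=series.values,
        phase=["baseline"] * series.n_baseline
        + ["hyperemia"] * (len(series) - series.n_baseline),
        params=params,
        seed=int(seed),
    )
    return rec, manifest


def simulate_cohort(
    group_sizes: Sequence[int] = (30, 40, 40, 30),
    master_seed: int = 0,
    render: bool = False,
    protocol: Optional[ProtocolSpec] = None,
) -> list[dict]:
    """Simulate a four-group cohort (default sizes 30/40/40/30 → 140 subjects).

    Per-subject seeds derive deterministically from ``master_seed`` via a
    SeedSequence.  Each entry carries the subject's group label, metadata,
    amplitude series, manifest and — when ``render`` is true — the rendered
    recording.
    """
    if len(group_sizes) != 4:
        raise ValueError("expected sizes for 4 groups")
    protocol = protocol or ProtocolSpec()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(int(sum(group_sizes)))
    subjects = []
    idx = 0
    for group, size in zip((1, 2, 3, 4), group_sizes):
        params = ARCHETYPES[group]
        for k in range(size):
            seed = int(children[idx].generate_state(1)[0] % (2**31))
            series, manifest = simulate_amplitude_series(
                params, seed=seed, protocol=protocol
            )
            subject = {
                "subject_id": f"g{group}s{k + 1:02d}",
                "group": group,
                "seed": seed,
                "meta": dict(_GROUP_META[group]),
                "series": series,
                "manifest": manifest,
            }
            if render:
                rec, manifest = render_waveform(
                    series, params, seed=seed + 1, protocol=protocol
                )
                subject["recording"] = rec
                subject["manifest"] = manifest
            subjects.append(subject)
            idx += 1
    return subjects


def write_subject(subject: dict, out_dir: str | Path, fs_hz: float = 500.0) -> dict:
    """Write one simulated subject to disk: recording CSV (if rendered) and
    ground-truth JSON.  Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    sid = subject["subject_id"]
    gt_path = out_dir / f"{sid}_truth.json"
    gt_path.write_text(json.dumps(subject["manifest"].to_dict()) + "\n")
    paths["truth"] = gt_path
    if "recording" in subject:
        rec_path = out_dir / f"{sid}.csv"
        np.savetxt(rec_path, subject["recording"].samples, fmt="%.6f")
        paths["recording"] = rec_path
    return paths
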