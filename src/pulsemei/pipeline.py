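"""End-to-end analysis: recording → phases → beats → amplitude series →
EMD detrend → multiscale entropy indices and dilatation index."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

from . import beat_detection, emd_detrend, entropy, hemodynamics, signal_model
from .signal_model import AmplitudeSeries, PulseRecording

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_recording", "analyze_series"]

log = logging.getLogger("pulsemei")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every knob of the analysis in one place, for provenance hashing."""

    min_hr_bpm: float = 40.0
    max_hr_bpm: float = 150.0
    n_beats: Optional[int] = None
    emd: emd_detrend.EMDConfig = field(default_factory=emd_detrend.EMDConfig)
    mse: entropy.MSEConfig = field(default_factory=entropy.MSEConfig)
    windows: hemodynamics.WindowPolicy = field(default_factory=hemodynamics.WindowPolicy)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisResult:
    """Analysis outputs plus the audit trail of how they were obtained."""

    di: hemodynamics.DIResult
    mei: entropy.MEIResult
    n_beats: int
    phase_split: int
    r_used: float
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "di": self.di.to_dict(),
            "mei": self.mei.to_dict(),
            "n_beats": self.n_beats,
            "phase_split": self.phase_split,
            "r_used": self.r_used,
            "config_hash": self.config_hash,
        }


def analyze_series(
    series: AmplitudeSeries,
    config: Optional[AnalysisConfig] = None,
    protocol: Optional[signal_model.ProtocolSpec] = None,
) -> AnalysisResult:
    """Analyze an already-extracted beat-amplitude series (DI + detrend + MEI)."""
    config = config or AnalysisConfig()
    di = hemodynamics.compute_di(series, protocol, config.windows)
    detrended = emd_detrend.detrend(series, config.emd)
    curve = entropy.mse_curve(detrended, config.mse)
    mei_result = entropy.mei(curve)
    flagged = [int(t) for t, f in zip(curve.tau, curve.flags) if f != entropy.FLAG_OK]
    chash = signal_model.config_hash(config.to_dict())
    log.info(
        "analysis: config=%s beats=%d split=%d r=%.6g flagged_scales=%s",
        chash, len(series), series.phase_split, curve.r_used[0], flagged,
    )
    return AnalysisResult(
        di=di,
        mei=mei_result,
        n_beats=len(series),
        phase_split=series.phase_split,
        r_used=float(curve.r_used[0]),
        config_hash=chash,
    )


def analyze_recording(
    rec: PulseRecording,
    config: Optional[AnalysisConfig] = None,
) -> AnalysisResult:
    """Run the full pipeline on a sampled recording.

    Occlusion-phase samples are discarded; baseline and hyperemic beats are
    detected separately and concatenated before detrending and entropy
    analysis.
    """
    config = config or AnalysisConfig()
    phases = signal_model.segment_phases(rec)
    base_beats = beat_detection.detect_beats(
        rec, phases.baseline, config.min_hr_bpm, config.max_hr_bpm
    )
    hyp_beats = beat_detection.detect_beats(
        rec, phases.hyperemia, config.min_hr_bpm, config.max_hr_bpm
    )
    series = beat_detection.build_amplitude_series(
        base_beats, hyp_beats, fs_hz=rec.fs_hz, n_beats=config.n_beats
    )
    return analyze_series(series, config, rec.protocol)
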