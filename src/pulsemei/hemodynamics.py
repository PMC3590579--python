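"""Dilatation index (DI) from phase-windowed mean beat amplitudes.

DI = Amp_RH / Amp_Baseline × 100 %, where Amp_Baseline and Amp_RH are the
mean beat amplitudes inside one representative 60-s window of the baseline
and hyperemic phases respectively.  A healthy endothelium roughly doubles
the pulse amplitude after cuff release (DI near 200 %); impaired dilation
shows as a lower ratio.

Window placement is configurable because the representative minute is a
choice, not a measurement: by default the baseline window is the last 60 s
of the baseline phase (closest to occlusion, after the subject has settled)
and the hyperemic window is the 60-s window, stepped at 10 s over the first
180 s of hyperemia, that maximizes the mean amplitude — i.e. the window
capturing the hyperemic peak.  A fixed-offset policy is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signal_model import AmplitudeSeries, ProtocolSpec

__all__ = ["WindowPolicy", "DIResult", "window_mean_amplitude", "dilatation_index", "select_windows", "compute_di"]

MIN_BEATS_PER_WINDOW = 5


@dataclass(frozen=True)
class WindowPolicy:
    """Placement of the two representative windows.

    rh_policy "max" slides a window over the early hyperemic phase and keeps
    the one with the largest mean amplitude; "fixed" places it at
    ``rh_offset_s`` after hyperemia onset.
    """

    width_s: float = 60.0
    rh_policy: str = "max"
    rh_search_s: float = 180.0
    rh_step_s: float = 10.0
    rh_offset_s: float = 0.0
    baseline_offset_from_end_s: float = 60.0

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("window width must be > 0")
        if self.rh_policy not in ("max", "fixed"):
            raise ValueError(f"unknown rh_policy {self.rh_policy!r}")


@dataclass
class DIResult:
    """Dilatation-index result with the windows used, for auditability."""

    amp_baseline: float
    amp_rh: float
    di_percent: float
    windows: dict

    def __post_init__(self) -> None:
        if self.amp_baseline <= 0:
            raise ValueError("baseline amplitude must be positive")

    def to_dict(self) -> dict:
        return {
            "amp_baseline": self.amp_baseline,
            "amp_rh": self.amp_rh,
            "di_percent": self.di_percent,
            "windows": self.windows,
        }


def window_mean_amplitude(series: AmplitudeSeries, window: tuple[float, float]) -> float:
    """Mean beat amplitude over a half-open time window [start, stop) seconds."""
    start, stop = window
    mask = (series.beat_times_s >= start) & (series.beat_times_s < stop)
    n = int(np.count_nonzero(mask))
    if n < MIN_BEATS_PER_WINDOW:
        raise ValueError(
            f"window [{start:.0f}, {stop:.0f}) s contains {n} beats "
            f"(need >= {MIN_BEATS_PER_WINDOW})"
        )
    return float(np.mean(series.values[mask]))


def dilatation_index(amp_baseline: float, amp_rh: float,
                     windows: Optional[dict] = None) -> DIResult:
    """DI = Amp_RH / Amp_Baseline × 100 (%)."""
    if amp_baseline <= 0 or amp_rh <= 0:
        raise ValueError("amplitudes must be positive")
    return DIResult(
        amp_baseline=float(amp_baseline),
        amp_rh=float(amp_rh),
        di_percent=float(amp_rh / amp_baseline * 100.0),
        windows=windows or {},
    )


def select_windows(
    series: AmplitudeSeries,
    protocol: Optional[ProtocolSpec] = None,
    policy: Optional[WindowPolicy] = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Choose the representative baseline and hyperemic 60-s windows.

    Returns two (start, stop) time ranges in recording seconds.  Raises when
    a phase is shorter than the window width.
    """
    protocol = protocol or ProtocolSpec()
    policy = policy or WindowPolicy()
    w = policy.width_s
    if protocol.baseline_s < w or protocol.hyperemia_s < w:
        raise ValueError(f"phase shorter than the {w:.0f}-s window")
    b_end = protocol.baseline_s
    baseline_win = (b_end - policy.baseline_offset_from_end_s,
                    b_end - policy.baseline_offset_from_end_s + w)
    h_start = protocol.baseline_s + protocol.occlusion_s
    if policy.rh_policy == "fixed":
        rh_win = (h_start + policy.rh_offset_s, h_start + policy.rh_offset_s + w)
        return baseline_win, rh_win
    best_win, best_mean = None, -np.inf
    search_end = min(policy.rh_search_s, protocol.hyperemia_s) - w
    offsets = np.arange(0.0, search_end + 1e-9, policy.rh_step_s)
    for off in offsets:
        win = (h_start + off, h_start + off + w)
        try:
            m = window_mean_amplitude(series, win)
        except ValueError:
            continue
        if m > best_mean:
            best_mean, best_win = m, win
    if best_win is None:
        raise ValueError("no hyperemic window with enough beats")
    return baseline_win, best_win


def compute_di(
    series: AmplitudeSeries,
    protocol: Optional[ProtocolSpec] = None,
    policy: Optional[WindowPolicy] = None,
) -> DIResult:
    """Full DI computation: select windows, average amplitudes, form the ratio."""
    baseline_win, rh_win = select_windows(series, protocol, policy)
    amp_b = window_mean_amplitude(series, baseline_win)
    amp_rh = window_mean_amplitude(series, rh_win)
    return dilatation_index(
        amp_b,
        amp_rh,
        windows={"baseline": list(baseline_win), "rh": list(rh_win)},
    )
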