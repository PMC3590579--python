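"""Empirical mode decomposition (EMD) and trend removal for beat-amplitude series.

EMD sifts a series into a small set of intrinsic mode functions (IMFs),
ordered fast to slow, plus a non-oscillatory residue.  The hyperemic
amplitude envelope makes the raw beat-amplitude curve strongly
nonstationary, which would bias sample-entropy matching; subtracting the
EMD trend (the residue, optionally plus the slowest IMFs) restores an
approximately zero-mean stationary fluctuation series.

Implementation choices (classical Huang-style EMD, fully deterministic):
cubic-spline envelopes through local maxima/minima with mirror extension of
two extrema at each boundary; Cauchy sift stopping criterion SD < 0.2 with a
cap of 100 sifts per IMF; decomposition stops when the residue has fewer
than 4 extrema.  No ensemble (noise-assisted) variant is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .signal_model import AmplitudeSeries, DetrendedSeries

__all__ = ["EMDConfig", "IMFSet", "emd", "detrend"]


@dataclass(frozen=True)
class EMDConfig:
    """Sift settings and the trend definition used by :func:`detrend`.

    The trend is always the residue; in addition every IMF whose mean period
    (2N / extrema count) exceeds ``trend_period_frac`` × N joins the trend —
    EMD splits a slow, bump-shaped drift between the residue and the slowest
    IMFs, so a residue-only trend systematically under-removes it.  Set
    ``trend_period_frac = None`` for a residue-only trend; ``trend_imfs``
    forces that many of the slowest remaining IMFs into the trend on top of
    the adaptive rule.
    """

    sift_sd_threshold: float = 0.2
    max_sifts: int = 100
    max_imfs: int = 12
    trend_imfs: int = 0
    trend_period_frac: Optional[float] = 0.1

    def __post_init__(self) -> None:
        if self.sift_sd_threshold <= 0:
            raise ValueError("sift_sd_threshold must be > 0")
        if self.max_sifts < 1 or self.max_imfs < 1:
            raise ValueError("max_sifts and max_imfs must be >= 1")
        if self.trend_imfs < 0:
            raise ValueError("trend_imfs must be >= 0")
        if self.trend_period_frac is not None and not 0 < self.trend_period_frac <= 1:
            raise ValueError("trend_period_frac must lie in (0, 1] or be None")


@dataclass
class IMFSet:
    """Ordered IMFs (fast → slow) plus the final residue.

    ``sum(imfs) + residue`` reconstructs the input exactly (the residue is
    computed by subtraction, so completeness holds to float round-off).
    """

    imfs: list
    residue: np.ndarray
    n_sifts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.imfs = [np.asarray(c, dtype=float) for c in self.imfs]
        self.residue = np.asarray(self.residue, dtype=float)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def to_frame(self):
        """IMFs + residue as a DataFrame (one column per component)."""
        import pandas as pd

        data = {f"imf{i + 1}": c for i, c in enumerate(self.imfs)}
        data["residue"] = self.residue
        return pd.DataFrame(data)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints included)."""
    d = np.sign(np.diff(x))
    # collapse flat segments so plateaus register a single extremum
    nz = np.flatnonzero(d)
    maxima, minima = [], []
    for a, b in zip(nz[:-1], nz[1:]):
        if d[a] > 0 and d[b] < 0:
            maxima.append((a + 1 + b) // 2 if x[a + 1] == x[b] else b)
        elif d[a] < 0 and d[b] > 0:
            minima.append((a + 1 + b) // 2 if x[a + 1] == x[b] else b)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirror_extend(idx: np.ndarray, vals: np.ndarray, n: int, n_ext: int = 2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to ``n_ext`` extrema beyond each boundary of a series of length n."""
    left_i = (-idx[:n_ext][::-1]).astype(float)
    left_v = vals[:n_ext][::-1]
    right_i = (2 * (n - 1) - idx[-n_ext:][::-1]).astype(float)
    right_v = vals[-n_ext:][::-1]
    xi = np.concatenate([left_i, idx.astype(float), right_i])
    yi = np.concatenate([left_v, vals, right_v])
    keep = np.concatenate([[True], np.diff(xi) > 0])
    return xi[keep], yi[keep]


def _is_imf_like(x: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    max_i, min_i = _local_extrema(x)
    sign = np.sign(x)
    sign[sign == 0] = 1
    zc = int(np.count_nonzero(np.diff(sign)))
    return abs((max_i.size + min_i.size) - zc) <= 1


def _mean_envelope(x: np.ndarray) -> Optional[np.ndarray]:
    """Mean of the upper and lower cubic-spline envelopes; None if x lacks
    enough extrema to define them."""
    max_i, min_i = _local_extrema(x)
    if max_i.size < 2 or min_i.size < 2:
        return None
    n = x.size
    t = np.arange(n, dtype=float)
    ux, uy = _mirror_extend(max_i, x[max_i], n)
    lx, ly = _mirror_extend(min_i, x[min_i], n)
    upper = CubicSpline(ux, uy)(t)
    lower = CubicSpline(lx, ly)(t)
    return 0.5 * (upper + lower)


def emd(series: Sequence[float], config: Optional[EMDConfig] = None) -> IMFSet:
    """Decompose a series into IMFs plus residue.

    Monotonic (or otherwise extrema-poor) input yields zero IMFs with the
    residue equal to the input — not an error.  Non-finite input raises.
    """
    config = config or EMDConfig()
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError(f"series too short for EMD: {x.size} < 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in EMD input")

    imfs: list[np.ndarray] = []
    n_sifts: list[int] = []
    residue = x.copy()
    for _ in range(config.max_imfs):
        max_i, min_i = _local_extrema(residue)
        if max_i.size + min_i.size < 4:
            break  # residue is the final trend
        h = residue.copy()
        sifts = 0
        while sifts < config.max_sifts:
            env = _mean_envelope(h)
            if env is None:
                break
            h_new = h - env
            sifts += 1
            denom = float(np.sum(h * h))
            if denom == 0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < config.sift_sd_threshold and _is_imf_like(h):
                break
        if sifts == 0:
            break
        imfs.append(h)
        n_sifts.append(sifts)
        residue = residue - h
    return IMFSet(imfs=imfs, residue=residue, n_sifts=n_sifts)


def imf_mean_period(imf: np.ndarray) -> float:
    """Mean oscillation period of an IMF in samples, 2N / (number of extrema)."""
    max_i, min_i = _local_extrema(imf)
    n_ext = max_i.size + min_i.size
    return math.inf if n_ext == 0 else 2.0 * imf.size / n_ext


def detrend(series: AmplitudeSeries, config: Optional[EMDConfig] = None) -> DetrendedSeries:
    """Remove the EMD trend from a beat-amplitude series.

    The trend is the residue plus every IMF slower than
    ``trend_period_frac`` × series length, plus ``trend_imfs`` further
    slowest IMFs if configured.  The detrended values plus the trend
    reconstruct the source exactly.
    """
    config = config or EMDConfig()
    decomp = emd(series.values, config)
    n = series.values.size
    trend = decomp.residue.copy()
    in_trend = [False] * decomp.n_imfs
    if config.trend_period_frac is not None:
        cutoff = config.trend_period_frac * n
        for i, c in enumerate(decomp.imfs):
            if imf_mean_period(c) > cutoff:
                in_trend[i] = True
    remaining = [i for i in range(decomp.n_imfs) if not in_trend[i]]
    for i in remaining[len(remaining) - min(config.trend_imfs, len(remaining)):]:
        in_trend[i] = True
    for i, c in enumerate(decomp.imfs):
        if in_trend[i]:
            trend = trend + c
    values = series.values - trend
    return DetrendedSeries(values=values, trend=trend, source=series)
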