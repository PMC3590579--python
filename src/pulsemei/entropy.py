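"""Coarse-graining, sample entropy, the multiscale entropy curve, and the
small-/large-scale multiscale entropy indices (MEI_SS, MEI_LS).

Sample entropy S_E(m, r) is the negative natural log of the conditional
probability that two sequences matching for m points (Chebyshev distance
within tolerance r, self-matches excluded) also match at the (m+1)-th point.
The multiscale curve evaluates S_E on non-overlapping block averages of the
series at scale factors τ = 1..τ_max; MEI_SS sums scales 1–5 and MEI_LS sums
scales 6–10, separating fast beat-to-beat irregularity from slower
fluctuation structure.

Defaults follow the Costa convention: m = 2, r = 0.15 × SD of the scale-1
series, with r held fixed across scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .signal_model import DetrendedSeries

__all__ = [
    "MSEConfig",
    "MSECurve",
    "MEIResult",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "mei",
]

#: per-scale degeneracy flags
FLAG_OK = "ok"
FLAG_NO_M_MATCHES = "no_m_matches"      # B = 0 -> S_E undefined (NaN)
FLAG_NO_M1_MATCHES = "no_m1_matches"    # A = 0, B > 0 -> S_E = +inf


@dataclass(frozen=True)
class MSEConfig:
    """Parameters of the multiscale sample-entropy analysis.

    r_mode "fraction_of_sd" interprets r_value as a fraction of the series
    SD (computed once from the scale-1 series when r_fixed_across_scales,
    else per scale); "absolute" uses r_value in the units of the data.
    """

    m: int = 2
    r_mode: str = "fraction_of_sd"
    r_value: float = 0.15
    tau_max: int = 10
    r_fixed_across_scales: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r_value <= 0:
            raise ValueError(f"r_value must be > 0, got {self.r_value}")
        if self.tau_max < 1:
            raise ValueError(f"tau_max must be >= 1, got {self.tau_max}")
        if self.r_mode not in ("fraction_of_sd", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class MSECurve:
    """Sample entropy versus scale factor, with per-scale lengths and flags."""

    tau: np.ndarray
    s_e: np.ndarray
    n_tau: np.ndarray
    flags: list
    r_used: np.ndarray = field(default=None)  # tolerance actually applied per scale

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=int)
        self.s_e = np.asarray(self.s_e, dtype=float)
        self.n_tau = np.asarray(self.n_tau, dtype=int)
        if self.r_used is None:
            self.r_used = np.full(self.tau.size, np.nan)
        self.r_used = np.asarray(self.r_used, dtype=float)
        k = self.tau.size
        if not (self.s_e.size == self.n_tau.size == len(self.flags) == k):
            raise ValueError("tau/s_e/n_tau/flags lengths differ")
        defined = np.isfinite(self.s_e)
        if np.any(self.s_e[defined] < 0):
            raise ValueError("sample entropy cannot be negative")

    def to_dict(self) -> dict:
        return {
            "tau": self.tau.tolist(),
            "s_e": [float(v) if math.isfinite(v) else None for v in self.s_e],
            "n_tau": self.n_tau.tolist(),
            "flags": list(self.flags),
            "r_used": [float(v) if math.isfinite(v) else None for v in self.r_used],
        }

    def to_frame(self):
        """Per-scale curve as a DataFrame (tau, s_e, n, flag) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {"tau": self.tau, "s_e": self.s_e, "n": self.n_tau, "flag": self.flags}
        )


@dataclass
class MEIResult:
    """Small-scale and large-scale multiscale entropy indices.

    mei_ss = Σ_{τ=1..5} S_E(τ); mei_ls = Σ_{τ=6..10} S_E(τ).  If any scale in
    a band is degenerate the containing index is NaN and ``defined`` is False.
    """

    mei_ss: float
    mei_ls: float
    curve: MSECurve

    @property
    def defined(self) -> bool:
        return math.isfinite(self.mei_ss) and math.isfinite(self.mei_ls)

    def to_dict(self) -> dict:
        return {
            "mei_ss": float(self.mei_ss) if math.isfinite(self.mei_ss) else None,
            "mei_ls": float(self.mei_ls) if math.isfinite(self.mei_ls) else None,
            "curve": self.curve.to_dict(),
        }


def coarse_grain(x: Sequence[float], tau: int) -> np.ndarray:
    """Non-overlapping block average of ``x`` at scale factor ``tau``.

    y_j = mean(x[(j-1)τ .. jτ-1]) for j = 1..floor(N/τ); trailing remainder
    samples are discarded.  At τ = 1 the coarse-grained series is the
    original series.
    """
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    if tau > x.size:
        raise ValueError(f"tau={tau} exceeds series length {x.size}")
    if tau == 1:
        return x.copy()
    n = x.size // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(x: Sequence[float], m: int = 2, r: float = 0.15) -> float:
    """Sample entropy S_E = −ln(A/B) with tolerance ``r`` in the units of ``x``.

    B counts unordered template pairs i < j (i, j ≤ N−m, so that both the
    m- and (m+1)-length templates exist) whose m-length templates match
    within Chebyshev distance r; A counts the same pairs at length m+1.
    Self-matches are excluded.  Degenerate outcomes: B = 0 returns NaN
    (undefined), A = 0 with B > 0 returns +inf.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if r <= 0:
        raise ValueError("degenerate tolerance: r must be > 0")
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m}")
    nt = n - m  # number of templates of length m (and of length m+1)
    # running Chebyshev distance between template pairs, built one lag at a time
    cheb = np.zeros((nt, nt))
    for k in range(m):
        seg = x[k : k + nt]
        np.maximum(cheb, np.abs(seg[:, None] - seg[None, :]), out=cheb)
    iu = np.triu_indices(nt, k=1)
    match_m = cheb[iu] <= r
    b = int(np.count_nonzero(match_m))
    if b == 0:
        return math.nan
    seg = x[m : m + nt]
    np.maximum(cheb, np.abs(seg[:, None] - seg[None, :]), out=cheb)
    a = int(np.count_nonzero(cheb[iu] <= r))
    if a == 0:
        return math.inf
    return -math.log(a / b)


def _resolve_r(x: np.ndarray, cfg: MSEConfig) -> float:
    if cfg.r_mode == "absolute":
        return cfg.r_value
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("degenerate tolerance: SD of series is zero under fraction_of_sd mode")
    return cfg.r_value * sd


def mse_curve(
    x: Union[DetrendedSeries, Sequence[float]],
    cfg: Optional[MSEConfig] = None,
) -> MSECurve:
    """Multiscale entropy curve S_E(τ), τ = 1..cfg.tau_max.

    Accepts a detrended amplitude series or any numeric sequence.  With the
    default configuration the tolerance is computed once from the scale-1
    series SD and held fixed across scales.  Degenerate scales are flagged in
    the curve rather than raising.
    """
    cfg = cfg or MSEConfig()
    values = x.values if isinstance(x, DetrendedSeries) else np.asarray(x, dtype=float)
    if values.size < cfg.tau_max * (cfg.m + 2):
        raise ValueError(
            f"series of length {values.size} too short for tau_max={cfg.tau_max}, m={cfg.m}"
        )
    r_global = _resolve_r(values, cfg) if cfg.r_fixed_across_scales or cfg.r_mode == "absolute" else None
    taus = np.arange(1, cfg.tau_max + 1)
    s_e = np.empty(taus.size)
    n_tau = np.empty(taus.size, dtype=int)
    r_used = np.empty(taus.size)
    flags = []
    for i, tau in enumerate(taus):
        y = coarse_grain(values, int(tau))
        n_tau[i] = y.size
        r = r_global if r_global is not None else _resolve_r(y, cfg)
        r_used[i] = r
        v = sample_entropy(y, cfg.m, r)
        s_e[i] = v
        if math.isnan(v):
            flags.append(FLAG_NO_M_MATCHES)
        elif math.isinf(v):
            flags.append(FLAG_NO_M1_MATCHES)
        else:
            flags.append(FLAG_OK)
    return MSECurve(tau=taus, s_e=s_e, n_tau=n_tau, flags=flags, r_used=r_used)


def mei(curve: MSECurve) -> MEIResult:
    """Sum the entropy curve into MEI_SS (scales 1–5) and MEI_LS (scales 6–10).

    Requires scales 1..10; a degenerate scale makes its index NaN (flagged
    via the curve) rather than silently contributing zero.
    """
    if curve.tau.size < 10 or not np.array_equal(curve.tau[:10], np.arange(1, 11)):
        raise ValueError("MEI requires an entropy curve over scales 1..10")
    ss_vals = curve.s_e[:5]
    ls_vals = curve.s_e[5:10]
    mei_ss = float(np.sum(ss_vals)) if np.all(np.isfinite(ss_vals)) else math.nan
    mei_ls = float(np.sum(ls_vals)) if np.all(np.isfinite(ls_vals)) else math.nan
    return MEIResult(mei_ss=mei_ss, mei_ls=mei_ls, curve=curve)
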