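"""Standard heart-rate-variability observables on RR-interval series.

Time-domain summaries (mean RR, SDNN, rMSSD), spectral band powers on the
evenly resampled tachogram (VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz,
HF 0.15-0.4 Hz), detrended fluctuation analysis (short-range alpha1 over
4-16 beats, long-range alpha2 over 16-64 beats), and the low-frequency
spectral scaling ``S(f) ~ 1/f**(2H-1)`` of the increment series.

RR input files are plain text, one interval in milliseconds per line,
``#``-prefixed comment lines ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as _signal
from scipy.interpolate import CubicSpline

from .errors import DataError, InsufficientDataError, ParameterError

__all__ = [
    "RRSeries",
    "HRVReport",
    "time_domain",
    "frequency_domain",
    "dfa",
    "dfa_fluctuation",
    "spectrum_scaling",
    "hrv_report",
]

BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


@dataclass(frozen=True)
class RRSeries:
    """An ordered series of inter-beat (RR) intervals in milliseconds."""

    intervals: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.intervals, dtype=float).ravel()
        object.__setattr__(self, "intervals", v)
        if v.size < 2:
            raise DataError("an RR series needs at least 2 intervals")
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise DataError("all RR intervals must be finite and > 0 ms")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration_s(self) -> float:
        """Total recording length in seconds."""
        return float(self.intervals.sum() / 1000.0)

    def increments(self) -> np.ndarray:
        """First differences I(n) = B(n+1) - B(n), in ms."""
        return np.diff(self.intervals)

    @classmethod
    def from_file(cls, path, label: str | None = None) -> "RRSeries":
        path = Path(path)
        vals = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals.append(float(line))
            except ValueError as exc:
                raise DataError(
                    f"{path.name}:{lineno}: cannot parse RR interval {line!r}"
                ) from exc
        if len(vals) < 2:
            raise DataError(f"{path.name}: fewer than 2 RR intervals")
        return cls(np.array(vals), label=label if label is not None else path.stem)

    def to_file(self, path) -> None:
        lines = [f"# RR intervals (ms); label={self.label}"]
        lines += [f"{v:.6g}" for v in self.intervals]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class HRVReport:
    """The standard HRV observable battery for one recording."""

    mean_rr: float
    sdnn: float
    rmssd: float
    vlf_power: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    dfa_alpha1: float
    dfa_alpha2: float

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def summary(self) -> str:
        rows = [
            ("Mean RR, ms", self.mean_rr),
            ("SDNN, ms", self.sdnn),
            ("rMSSD, ms", self.rmssd),
            ("VLF power, ms^2", self.vlf_power),
            ("LF power, ms^2", self.lf_power),
            ("HF power, ms^2", self.hf_power),
            ("LF/HF ratio", self.lf_hf_ratio),
            ("DFA alpha1", self.dfa_alpha1),
            ("DFA alpha2", self.dfa_alpha2),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}} {v:10.3f}" for k, v in rows)


def time_domain(rr: RRSeries) -> tuple[float, float, float]:
    """Mean RR, SDNN (sample SD of intervals) and rMSSD (root mean square of
    successive differences), all in ms."""
    b = rr.intervals
    if b.size < 3:
        raise InsufficientDataError("need >= 3 intervals for rMSSD")
    mean_rr = float(b.mean())
    sdnn = float(b.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(b) ** 2)))
    return mean_rr, sdnn, rmssd


def _resample_tachogram(rr: RRSeries, fs: float) -> np.ndarray:
    t = np.cumsum(rr.intervals) / 1000.0  # beat times, s
    t = t - t[0]
    spline = CubicSpline(t, rr.intervals)
    grid = np.arange(0.0, t[-1], 1.0 / fs)
    return spline(grid)


def frequency_domain(
    rr: RRSeries, fs: float = 4.0, nperseg_s: float = 256.0
) -> tuple[float, float, float, float]:
    """Band powers (ms^2) of the RR tachogram and the LF/HF ratio.

    The irregularly sampled tachogram is cubic-spline resampled at ``fs`` Hz
    and the spectrum estimated by Welch averaging (Hann taper, segments of
    ``nperseg_s`` seconds, 50% overlap).  Band power is the PSD integral over
    the band, so total in-band power equals the sum of the three bands.
    """
    if rr.duration_s < 300.0:
        raise InsufficientDataError(
            f"frequency-domain indices need >= 5 min of data, got {rr.duration_s:.0f} s"
        )
    x = _resample_tachogram(rr, fs)
    nperseg = min(int(nperseg_s * fs), x.size)
    f, psd = _signal.welch(
        x - x.mean(), fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    powers = {}
    for name, (lo, hi) in BANDS.items():
        m = (f >= lo) & (f < hi)
        powers[name] = float(np.trapezoid(psd[m], f[m]))
    ratio = powers["lf"] / powers["hf"] if powers["hf"] > 0 else float("inf")
    return powers["vlf"], powers["lf"], powers["hf"], ratio


from functools import lru_cache


@lru_cache(maxsize=256)
def _white_noise_f2(s: int) -> float:
    """Exact E[F^2(s)] of DFA-1 for unit-variance white noise input.

    The integrated series is a random walk with covariance C_ij = min(i,j)+1;
    with M the linear-detrend residual projector, E[F^2] = tr(M C M)/s.
    Used to divide out the finite-size distortion of small scales (the
    'modified DFA' correction), so white noise scales exactly as s**0.5.
    """
    t = np.arange(s, dtype=float)
    A = np.column_stack([t, np.ones(s)])
    M = np.eye(s) - A @ np.linalg.solve(A.T @ A, A.T)
    C = np.minimum.outer(t, t) + 1.0
    return float(np.trace(M @ C @ M.T) / s)


def dfa_fluctuation(series, scales, correct_bias: bool = True) -> np.ndarray:
    """DFA-1 fluctuation function F(s): RMS of linear-detrend residuals of the
    integrated, mean-centred series over non-overlapping windows of s points.

    With ``correct_bias`` (default) F(s) is divided by the white-noise
    finite-size shape ``sqrt(E_white[F^2(s)] / s)``, which removes the
    small-scale distortion of plain DFA-1 without affecting large scales.
    """
    x = np.asarray(series, dtype=float).ravel()
    y = np.cumsum(x - x.mean())
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        s = int(s)
        n_win = y.size // s
        if n_win < 2:
            raise InsufficientDataError(f"series too short for DFA scale {s}")
        seg = y[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        # per-window linear fit via least squares on the shared design
        A = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(A, seg.T, rcond=None)
        resid = seg.T - A @ coef
        out[i] = np.sqrt(np.mean(resid**2))
        if correct_bias:
            out[i] /= np.sqrt(_white_noise_f2(s) / s)
    return out


def _dfa_slope(series, lo: int, hi: int) -> float:
    scales = np.unique(np.geomspace(lo, hi, 10).astype(int))
    F = dfa_fluctuation(series, scales)
    return float(np.polyfit(np.log(scales), np.log(F), 1)[0])


def dfa(
    series,
    scale_range_1: tuple[int, int] = (4, 16),
    scale_range_2: tuple[int, int] = (16, 64),
) -> tuple[float, float]:
    """Short- and long-range DFA scaling exponents (alpha1, alpha2).

    First-order detrending; log-log slopes over 4-16 and 16-64 beats by
    default.  White noise gives alpha ~ 0.5, 1/f noise ~ 1.0, a random walk
    ~ 1.5; anti-correlated increments fall below 0.5.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4 * scale_range_2[1]:
        raise InsufficientDataError(
            f"need >= {4 * scale_range_2[1]} points for DFA, got {x.size}"
        )
    return _dfa_slope(x, *scale_range_1), _dfa_slope(x, *scale_range_2)


def spectrum_scaling(
    increments, band: tuple[float, float] = (0.004, 0.05)
) -> float:
    """Hurst-type exponent from the low-frequency increment spectrum.

    Fits the log-log slope ``-beta`` of the power spectrum (Welch, unit
    sampling rate in beats) over ``band`` (cycles/beat) and returns
    ``H = (beta + 1) / 2``, the exponent of the scaling law
    ``S(f) ~ 1/f**(2H - 1)``.  White-noise increments give H ~ 0.5.
    """
    x = np.asarray(increments, dtype=float).ravel()
    if x.size < 2**10:
        raise InsufficientDataError(f"need >= 1024 increments, got {x.size}")
    if x.std() == 0:
        raise DataError("degenerate (constant) increment series")
    nperseg = min(4096, x.size)
    f, psd = _signal.welch(x - x.mean(), fs=1.0, nperseg=nperseg, noverlap=nperseg // 2)
    m = (f >= band[0]) & (f <= band[1]) & (psd > 0)
    if m.sum() < 8:
        raise InsufficientDataError(
            f"band {band} holds only {int(m.sum())} spectral estimates (< 8)"
        )
    slope = np.polyfit(np.log(f[m]), np.log(psd[m]), 1)[0]
    beta = -float(slope)
    return (beta + 1.0) / 2.0


def hrv_report(rr: RRSeries) -> HRVReport:
    """Full Table-1-style observable battery for one RR series."""
    mean_rr, sdnn, rmssd = time_domain(rr)
    vlf, lf, hf, ratio = frequency_domain(rr)
    a1, a2 = dfa(rr.intervals)
    return HRVReport(
        mean_rr=mean_rr,
        sdnn=sdnn,
        rmssd=rmssd,
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=ratio,
        dfa_alpha1=a1,
        dfa_alpha2=a2,
    )
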