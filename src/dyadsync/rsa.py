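"""Time-varying RSA estimation from interbeat intervals.

The estimator follows the standard short-time spectral recipe: the IBI series
is cubic-spline resampled onto a uniform grid (default 4 Hz), then for every
second with a full surrounding window (default 32 s) the windowed segment is
linearly detrended, tapered (DPSS multitaper by default, single Hann as a
fallback), the tapered periodograms are averaged, and the one-sided power
spectral density is integrated over the respiration band. The per-second
output is ln(band power in ms^2), assigned to the window's central second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.signal import detrend as _detrend
from scipy.signal.windows import dpss as _dpss

from .types import DiffSeries, IBISeries, RSASeries, UniformSeries


@dataclass(frozen=True)
class EstimatorConfig:
    """Configuration of the per-second RSA estimator."""

    resample_hz: float = 4.0
    window_s: int = 32
    band_lo: float = 0.12
    band_hi: float = 0.40
    taper: str = "dpss"        # "dpss" | "hann"
    n_tapers: int = 3
    taper_nw: float = 2.0
    detrend_window: bool = True
    log_output: bool = True
    log_floor: float = 1e-8    # ms^2; far below physiological band power

    def validate(self) -> None:
        if not (0 < self.band_lo < self.band_hi < self.resample_hz / 2):
            raise ValueError(
                "band must satisfy 0 < band_lo < band_hi < resample_hz/2, got "
                f"[{self.band_lo}, {self.band_hi}] at {self.resample_hz} Hz"
            )
        n_w = self.window_s * self.resample_hz
        if abs(n_w - round(n_w)) > 1e-9 or round(n_w) < 64:
            raise ValueError(
                f"window_s*resample_hz must be an integer >= 64, got {n_w}"
            )
        if self.taper not in ("dpss", "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")

    @property
    def n_window(self) -> int:
        return int(round(self.window_s * self.resample_hz))

    @property
    def half_window_s(self) -> int:
        return self.window_s // 2


def _tapers(cfg: EstimatorConfig) -> np.ndarray:
    """Taper matrix (K, n_window), each row with unit energy."""
    n = cfg.n_window
    if cfg.taper == "dpss":
        w = _dpss(n, cfg.taper_nw, Kmax=cfg.n_tapers)
        w = np.atleast_2d(w)
    else:
        h = np.hanning(n)
        w = h[None, :]
    return w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))


def taper_second_weights(cfg: EstimatorConfig) -> np.ndarray:
    """Per-second energy profile of the taper set across the window
    (length ``window_s``, sums to 1). This is the effective weighting the
    short-time estimator applies to slowly varying signal power, used by
    ground-truth oracles."""
    w = (_tapers(cfg) ** 2).mean(axis=0)
    per_second = w.reshape(cfg.window_s, int(round(cfg.resample_hz))).sum(axis=1)
    return per_second / per_second.sum()


def resample_ibi(ibi: IBISeries, cfg: EstimatorConfig, task_length_s: int | None = None) -> UniformSeries:
    """Cubic-spline interpolate interval (ms) against beat time onto a
    uniform grid from t=0; samples outside the observed beat span are invalid
    (no extrapolation)."""
    cfg.validate()
    if ibi.n_beats < 4:
        raise ValueError(f"{ibi.person_id}: need >= 4 beats, got {ibi.n_beats}")
    if ibi.span_s < cfg.window_s:
        raise ValueError(
            f"{ibi.person_id}: task too short ({ibi.span_s:.1f} s < one "
            f"{cfg.window_s} s window)"
        )
    if task_length_s is None:
        task_length_s = int(math.ceil(ibi.beat_times[-1]))
    grid = np.arange(0, task_length_s, 1.0 / cfg.resample_hz)
    spline = CubicSpline(ibi.beat_times, ibi.intervals, extrapolate=False)
    values = spline(grid)
    valid = np.isfinite(values)
    values[~valid] = np.nan
    return UniformSeries(values=values, valid=valid, fs=cfg.resample_hz)


def band_power_psd(psd: np.ndarray, freqs: np.ndarray, band_lo: float, band_hi: float) -> np.ndarray:
    """Integrate a one-sided PSD over [band_lo, band_hi] (rectangle rule)."""
    df = freqs[1] - freqs[0]
    in_band = (freqs >= band_lo) & (freqs <= band_hi)
    return np.sum(psd[..., in_band], axis=-1) * df


def estimate_tv_rsa(uniform: UniformSeries, cfg: EstimatorConfig, person_id: str = "") -> RSASeries:
    """Per-second band power of the resampled IBI series.

    Second ``t`` uses the samples in [t - window/2, t + window/2); seconds
    without a full all-valid window are invalid.
    """
    cfg.validate()
    fs = cfg.resample_hz
    fs_int = int(round(fs))
    n_w = cfg.n_window
    half = cfg.half_window_s
    n_seconds = uniform.n_samples // fs_int

    values = np.full(n_seconds, np.nan)
    valid = np.zeros(n_seconds, dtype=bool)

    seconds = np.arange(n_seconds)
    starts = (seconds - half) * fs_int
    # first and last half-window seconds have no full surrounding window
    in_range = (seconds >= half) & (seconds < n_seconds - half) \
        & (starts + n_w <= uniform.n_samples)
    if not np.any(in_range):
        return RSASeries(person_id=person_id, values=values, valid=valid)

    x = np.where(uniform.valid, uniform.values, 0.0)
    win_vals = sliding_window_view(x, n_w)
    win_valid = sliding_window_view(uniform.valid, n_w)

    idx = starts[in_range]
    segs = win_vals[idx]                      # (n_ok, n_w)
    ok = win_valid[idx].all(axis=1)

    segs = segs - segs.mean(axis=1, keepdims=True)
    if cfg.detrend_window:
        segs = _detrend(segs, axis=1, type="linear")

    tapers = _tapers(cfg)                     # (K, n_w)
    spec = np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)
    freqs = np.fft.rfftfreq(n_w, d=1.0 / fs)
    # one-sided PSD per taper: 2|X|^2/fs except at DC and Nyquist
    scale = np.full(len(freqs), 2.0 / fs)
    scale[0] = 1.0 / fs
    if n_w % 2 == 0:
        scale[-1] = 1.0 / fs
    psd = (np.abs(spec) ** 2 * scale).mean(axis=1)  # (n_ok, n_freq)
    power = band_power_psd(psd, freqs, cfg.band_lo, cfg.band_hi)

    out_sec = seconds[in_range][ok]
    power = power[ok]
    if cfg.log_output:
        values[out_sec] = np.log(np.maximum(power, cfg.log_floor))
    else:
        values[out_sec] = power
    valid[out_sec] = True
    return RSASeries(person_id=person_id, values=values, valid=valid)


def remove_rsa_outliers(rsa: RSASeries, k: float = 3.0, two_sided: bool = True) -> RSASeries:
    """Invalidate seconds whose RSA deviates >= k SD from the person's task
    mean (two-sided by default; ``two_sided=False`` removes high values only).
    The input is not modified."""
    if rsa.n_valid < 2:
        raise ValueError(f"{rsa.person_id}: need >= 2 valid seconds")
    out = rsa.copy()
    if not np.isfinite(k):
        return out
    mean = rsa.mean
    sd = rsa.sd
    dev = out.values - mean
    if two_sided:
        outlier = np.abs(dev) >= k * sd
    else:
        outlier = dev >= k * sd
    out.valid &= ~outlier
    if out.n_valid == 0:
        raise ValueError(f"{rsa.person_id}: degenerate RSA series (all seconds removed)")
    return out


def first_difference(rsa: RSASeries) -> DiffSeries:
    """d(t) = value(t) - value(t-1), defined only where both seconds are
    valid; removes linear trends so downstream correlations reflect reactive
    change."""
    if rsa.n_valid < 2:
        raise ValueError(f"{rsa.person_id}: need >= 2 valid seconds")
    n = rsa.task_length_s
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n >= 2:
        both = rsa.valid[1:] & rsa.valid[:-1]
        values[1:][both] = rsa.values[1:][both] - rsa.values[:-1][both]
        valid[1:] = both
    return DiffSeries(person_id=rsa.person_id, values=values, valid=valid)


def estimate_rsa_series(
    ibi: IBISeries,
    cfg: EstimatorConfig,
    task_length_s: int | None = None,
    outlier_sd: float = 3.0,
) -> tuple[RSASeries, DiffSeries]:
    """Full per-person chain: resample, short-time band power, outlier
    removal, first difference."""
    uniform = resample_ibi(ibi, cfg, task_length_s=task_length_s)
    rsa = estimate_tv_rsa(uniform, cfg, person_id=ibi.person_id)
    cleaned = remove_rsa_outliers(rsa, k=outlier_sd)
    return cleaned, first_difference(cleaned)
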