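"""Forward sensor simulation and its inverse characterization.

The forward model is the standard Poisson--Gaussian camera model: expected
photons are converted to photo-electrons through the quantum efficiency,
shot noise is Poisson, read noise is additive Gaussian in electrons, and the
digitizer divides by the gain (electrons per ADU), adds a fixed offset and
rounds, clipping to the representable range.  The inverse problem is the
photon-transfer-curve calibration: the temporal variance of repeated frames
of a static scene grows linearly with the mean, with slope ``1/gain``;
departure from that line marks the end of the linear response.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SensorParams",
    "CalibrationResult",
    "DarkSeriesStats",
    "CalibrationUndefinedError",
    "load_sensor_preset",
    "simulate_sensor",
    "calibrate_mean_variance",
    "analyze_dark_series",
]


class CalibrationUndefinedError(ValueError):
    """Raised when a mean-variance calibration cannot be performed."""


@dataclass(frozen=True)
class SensorParams:
    """Gain/offset/noise description of a camera digitizer.

    Parameters
    ----------
    gain : float
        Conversion gain in electrons per ADU.
    offset : float
        Fixed digitizer offset in ADU.
    read_noise : float
        Read noise in electrons RMS.
    bit_depth : int
        Digitizer bit depth; output is clipped to ``[0, 2**bit_depth - 1]``.
    linear_max : float
        Upper bound of the linear response in ADU.  The response is modelled
        as hard-clipped there, so the mean-variance curve departs from the
        photon-transfer line above it.
    qe : float
        Quantum efficiency in (0, 1].
    """

    gain: float
    offset: float = 0.0
    read_noise: float = 0.0
    bit_depth: int = 12
    linear_max: float | None = None
    qe: float = 1.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")
        if self.read_noise < 0:
            raise ValueError(f"read_noise must be >= 0, got {self.read_noise}")
        if not 0 < self.qe <= 1:
            raise ValueError(f"qe must be in (0, 1], got {self.qe}")
        full_scale = 2**self.bit_depth - 1
        if self.linear_max is None:
            object.__setattr__(self, "linear_max", float(full_scale))
        if not 0 < self.linear_max <= full_scale:
            raise ValueError(
                f"linear_max must be in (0, {full_scale}], got {self.linear_max}"
            )

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class CalibrationResult:
    """Output of a photon-transfer-curve (mean-variance) calibration."""

    gain_est: float
    offset_est: float
    read_noise_est: float
    linear_max_est: float
    fit_points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gain_est > 0:
            raise ValueError("gain_est must be > 0")
        if not self.fit_points:
            raise ValueError("fit_points must be non-empty")


@dataclass
class DarkSeriesStats:
    """Temporal statistics of a dark-frame series."""

    mean_trace: np.ndarray
    drift_slope: float
    dip_period_frames: int | None
    dip_period_seconds: float | None


def load_sensor_preset(name: str) -> SensorParams:
    """Load a named :class:`SensorParams` preset shipped with the package."""
    text = (
        importlib.resources.files("blockstorm.data")
        .joinpath("sensor_presets.yaml")
        .read_text()
    )
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(
            f"unknown sensor preset {name!r}; available: {sorted(presets)}"
        )
    return SensorParams(**presets[name])


def simulate_sensor(
    photon_image: np.ndarray, params: SensorParams, seed: int
) -> np.ndarray:
    """Simulate the camera readout of an expected-photon image.

    Per pixel: ``electrons ~ Poisson(qe * photons) + N(0, read_noise)``;
    ``ADU = round(electrons / gain + offset)``, clipped to
    ``[0, min(linear_max, 2**bit_depth - 1)]``.

    Parameters
    ----------
    photon_image : ndarray
        2-D grid of expected photon counts (non-negative, finite).
    params : SensorParams
        Sensor description.
    seed : int
        Seed for the pixel noise; identical seeds give identical frames.

    Returns
    -------
    ndarray of float
        Integer-valued ADU frame (stored as float64 for downstream math).
    """
    photon_image = np.asarray(photon_image, dtype=np.float64)
    if not np.all(np.isfinite(photon_image)):
        raise ValueError("photon_image must be finite")
    if np.any(photon_image < 0):
        raise ValueError(
            "photon_image contains negative values; expected photon counts "
            "must be non-negative"
        )
    rng = np.random.default_rng(seed)
    electrons = rng.poisson(params.qe * photon_image).astype(np.float64)
    if params.read_noise > 0:
        electrons += rng.normal(0.0, params.read_noise, size=photon_image.shape)
    adu = np.rint(electrons / params.gain + params.offset)
    hi = min(float(params.linear_max), float(params.full_scale))
    return np.clip(adu, 0.0, hi)


def _binned_mean_variance(
    pix_mean: np.ndarray, pix_var: np.ndarray, n_bins: int = 60, min_count: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Trim the extreme tails: pixels land in the top/bottom bins partly by
    # having fluctuated there, which correlates bin mean with bin variance.
    lo = float(np.percentile(pix_mean, 0.2))
    hi = float(np.percentile(pix_mean, 99.8))
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    inside = (pix_mean >= lo) & (pix_mean <= hi)
    pm, pv = pix_mean[inside], pix_var[inside]
    idx = np.clip(np.digitize(pm, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sum_m = np.bincount(idx, weights=pm, minlength=n_bins)
    sum_v = np.bincount(idx, weights=pv, minlength=n_bins)
    keep = counts >= min_count
    if keep.sum() < 3:
        keep = counts >= max(2, min_count // 4)
    m = sum_m[keep] / counts[keep]
    v = sum_v[keep] / counts[keep]
    return m, v, counts[keep]


def _robust_line(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                 n_iter: int = 5) -> tuple[float, float]:
    """Weighted least-squares line with iterative >3-sigma residual rejection."""
    keep = np.ones(x.size, dtype=bool)
    slope = intercept = 0.0
    for _ in range(n_iter):
        slope, intercept = np.polyfit(x[keep], y[keep], 1, w=np.sqrt(w[keep]))
        resid = y - (slope * x + intercept)
        sigma = np.std(resid[keep])
        if sigma == 0:
            break
        new_keep = np.abs(resid) <= 3 * sigma
        new_keep[:2] = new_keep[:2] | keep[:2]  # never drop the anchor bins
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return float(slope), float(intercept)


def _censored_clip_z(var_ratio: float) -> float:
    """Distance (in noise sigmas) from a bin mean to the clip level.

    For X ~ N(mu, sigma^2) hard-clipped at L, Var(min(X, L)) / sigma^2 is a
    monotone function of z = (L - mu) / sigma; inverting it converts an
    observed variance sag into the clip level.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    def ratio(z: float) -> float:
        # moments of min(X, L) with X standard normal, clip at z
        phi, cdf = norm.pdf(z), norm.cdf(z)
        tail = 1.0 - cdf
        mean = -phi + z * tail  # E[min(X, z)]
        ex2 = cdf - z * phi + z * z * tail  # E[min(X, z)^2]
        return ex2 - mean * mean

    r = min(max(var_ratio, ratio(-2.0) + 1e-9), ratio(6.0) - 1e-9)
    return float(brentq(lambda z: ratio(z) - r, -2.0, 6.0))


def calibrate_mean_variance(
    frames: "list[np.ndarray] | np.ndarray",
    saturation_guard: float | str = "auto",
) -> CalibrationResult:
    """Photon-transfer-curve calibration from repeated frames of a static scene.

    Computes the per-pixel temporal mean and variance, bins pixels by mean,
    fits the linear low-intensity range of the variance-vs-mean curve and
    reads off the sensor parameters: ``gain = 1/slope``; the offset from the
    darkest pixels of the series (a calibration series should include a
    zero-flux region); the read noise from the intercept.  The first mean bin
    whose variance departs from the fitted line by more than 20% marks the
    end of the linear range.

    Parameters
    ----------
    frames : sequence of 2-D ndarray
        At least two same-shape frames of a static scene whose intensity is
        spread across pixels.
    saturation_guard : float or "auto"
        Upper ADU bound for points entering the fit; "auto" detects the
        breakpoint from the data.

    Returns
    -------
    CalibrationResult
    """
    stack = np.asarray(frames, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need at least 2 same-shape frames")
    n_frames = stack.shape[0]
    pix_mean = stack.mean(axis=0).ravel()
    pix_var = stack.var(axis=0, ddof=1).ravel()
    if float(pix_var.max()) == 0.0:
        raise CalibrationUndefinedError(
            "all pixels have zero temporal variance; calibration is undefined "
            "on noiseless input"
        )

    m, v, counts = _binned_mean_variance(pix_mean, pix_var)
    if isinstance(saturation_guard, (int, float)):
        sel = m <= float(saturation_guard)
        m, v, counts = m[sel], v[sel], counts[sel]

    # Seed the fit on the low-intensity quarter of the mean range, then grow
    # the linear region bin by bin while the relative deviation stays <= 20%.
    span = m.max() - m.min()
    seed_sel = m <= m.min() + max(0.25 * span, 1e-9)
    if seed_sel.sum() < 3:
        seed_sel = np.zeros_like(seed_sel)
        seed_sel[: max(3, m.size // 4)] = True
    order = np.argsort(m)
    m, v, counts = m[order], v[order], counts[order]
    seed_sel = seed_sel[order]
    slope, intercept = _robust_line(m[seed_sel], v[seed_sel], counts[seed_sel].astype(float))

    n_linear = int(seed_sel.sum())
    for i in range(n_linear, m.size):
        pred = slope * m[i] + intercept
        if pred <= 0 or abs(v[i] - pred) / pred > 0.20:
            break
        n_linear = i + 1
    slope, intercept = _robust_line(
        m[:n_linear], v[:n_linear], counts[:n_linear].astype(float)
    )
    # Re-evaluate the breakpoint with the refitted line.  A hard clip of the
    # response censors the pixel distribution, so the variance starts to sag
    # below the line about one noise-sigma *before* the clip level; invert
    # the censored-Gaussian variance ratio to place the breakpoint at the
    # clip level itself rather than at the censoring onset.
    pred_all = slope * m + intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        deviates = (pred_all > 0) & (np.abs(v - pred_all) / pred_all > 0.20)
    bp = None
    for i in range(n_linear, m.size):
        # a single deviating bin at the end of the range is noise, not a
        # breakpoint: require the departure to persist
        if deviates[i] and (i + 1 < m.size and deviates[i + 1]):
            ratio = v[i] / pred_all[i]
            if ratio < 1.0:
                z = _censored_clip_z(ratio)
                bp = float(m[i] + z * np.sqrt(pred_all[i]))
            else:
                bp = float(m[i])
            break
    linear_max_est = bp if bp is not None else float(pix_mean.max())

    if slope <= 0:
        raise CalibrationUndefinedError(
            "non-positive mean-variance slope; input does not follow a "
            "photon-transfer relation"
        )
    gain_est = 1.0 / slope

    # Offset: robust mean of the darkest pixels.  The temporal-mean noise
    # floor of those pixels (not of the whole scene) sets the selection band.
    m0 = float(np.percentile(pix_mean, 1.0))
    near_dark = pix_mean <= m0 + 1.0
    sigma_mean = float(
        np.sqrt(max(np.median(pix_var[near_dark]), 1e-12) / n_frames)
    )
    dark = pix_mean <= m0 + 4.0 * sigma_mean
    offset_est = float(pix_mean[dark].mean())

    # Intercept model: var = (mean-offset)/gain + rn^2/gain^2 + 1/12
    # (the 1/12 ADU^2 is quantization noise of the rounding step).
    rn_sq = gain_est**2 * (intercept - 1.0 / 12.0) + gain_est * offset_est
    read_noise_est = float(np.sqrt(max(rn_sq, 0.0)))

    return CalibrationResult(
        gain_est=float(gain_est),
        offset_est=offset_est,
        read_noise_est=read_noise_est,
        linear_max_est=float(linear_max_est),
        fit_points=[(float(a), float(b)) for a, b in zip(m[:n_linear], v[:n_linear])],
    )


def analyze_dark_series(stack: np.ndarray, fps: float) -> DarkSeriesStats:
    """Temporal analysis of a dark-frame series: drift and periodic dips.

    The per-frame spatial mean is detrended by a least-squares line; the dip
    period is the fundamental of the dominant autocorrelation peak.  A peak
    counts only if it exceeds 5x the median absolute deviation of the
    autocorrelation over all candidate lags.

    Parameters
    ----------
    stack : ndarray, shape (F, H, W) or (F,)
        Dark-frame sequence (or a precomputed per-frame mean trace).
    fps : float
        Acquisition frame rate, frames per second.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if fps <= 0:
        raise ValueError("fps must be > 0")
    trace = stack if stack.ndim == 1 else stack.mean(axis=(1, 2))
    n = trace.size
    if n < 64:
        raise ValueError(f"need >= 64 frames for period estimation, got {n}")

    t = np.arange(n, dtype=np.float64)
    drift_slope, intercept = np.polyfit(t, trace, 1)
    detrended = trace - (drift_slope * t + intercept)

    var = float(np.var(detrended))
    dip_frames: int | None = None
    if var > 0:
        d = detrended - detrended.mean()
        ac_full = np.correlate(d, d, mode="full")[n - 1 :]
        norm = np.arange(n, 0, -1, dtype=np.float64) * var
        ac = ac_full / norm
        lags = np.arange(2, n // 2)
        if lags.size >= 3:
            vals = ac[lags]
            mad = float(np.median(np.abs(vals - np.median(vals))))
            thresh = 5.0 * max(mad, 1e-12)
            # local maxima among candidate lags
            is_peak = np.zeros(lags.size, dtype=bool)
            is_peak[1:-1] = (vals[1:-1] >= vals[:-2]) & (vals[1:-1] >= vals[2:])
            sig = is_peak & (vals > thresh)
            if sig.any():
                best = int(lags[sig][np.argmax(vals[sig])])
                # prefer a sub-multiple carrying comparable correlation
                dip_frames = best
                for k in lags[sig]:
                    if best % int(k) == 0 and ac[int(k)] >= 0.5 * ac[best]:
                        dip_frames = int(k)
                        break
    return DarkSeriesStats(
        mean_trace=trace,
        drift_slope=float(drift_slope),
        dip_period_frames=dip_frames,
        dip_period_seconds=None if dip_frames is None else dip_frames / fps,
    )
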