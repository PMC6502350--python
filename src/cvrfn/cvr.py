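"""Voxel-wise BOLD cerebrovascular reactivity (CVR) mapping.

CVR is the percent BOLD signal change per mmHg change in end-tidal CO2
(PetCO2) and is estimated voxel by voxel from a BOLD run acquired during a
controlled CO2 step stimulus.  The stages are:

1. temporal smoothing of the percent-normalised BOLD series (zero-phase
   low-pass filter followed by robust loess),
2. interpolation of the CO2 trace onto the volume acquisition times,
3. voxel-wise hemodynamic lag estimation by cross-correlation against
   time-shifted copies of the CO2 regressor,
4. ordinary least-squares regression of percent signal on the lag-aligned
   regressor; the slope is CVR, and its t statistic forms the CVR t-map.

The CO2 regressor is passed through the same smoothing operator as the BOLD
data so that the smoothing is a common linear (affine-equivariant)
transformation of both sides of the regression and leaves the slope
unbiased.  Positive lag means the BOLD response follows the CO2 stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    ConfigurationError,
    CoverageError,
    CvrfnError,
    DegenerateRegressionError,
    DimensionError,
    ZeroBaselineError,
)

__all__ = [
    "Co2Trace",
    "BoldRun",
    "CvrResult",
    "CvrConfig",
    "make_analysis_mask",
    "temporal_smooth",
    "resample_co2",
    "estimate_lag",
    "fit_voxel_cvr",
    "compute_cvr_map",
]

#: reported t statistics are capped at this magnitude (noise-free voxels
#: have zero residual variance and a formally infinite t)
T_CAP = 1e6


@dataclass(frozen=True)
class Co2Trace:
    """Timestamped end-tidal CO2 partial-pressure series for one run.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing.
    petco2 : ndarray
        PetCO2 in mmHg at each sample time.
    """

    time: np.ndarray
    petco2: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.petco2, dtype=float)
        if t.ndim != 1 or t.shape != p.shape or t.size < 2:
            raise ConfigurationError("trace needs >=2 aligned (time, petco2) samples")
        if not np.all(np.diff(t) > 0):
            raise ConfigurationError("trace time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ConfigurationError("trace contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "petco2", p)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_csv(self, path):
        pd.DataFrame({"time_s": self.time, "petco2_mmHg": self.petco2}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Co2Trace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["petco2_mmHg"].to_numpy())


@dataclass
class BoldRun:
    """A 4D BOLD acquisition: ``data`` is (x, y, z, time) in scanner units."""

    data: np.ndarray
    tr: float
    condition: str = "normo"
    run_type: str = "cvr"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionError("BoldRun data must be 4D (x, y, z, t)")
        if self.data.shape[-1] < 10:
            raise ConfigurationError("runs shorter than 10 volumes are not supported")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.condition not in ("normo", "hyper"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.run_type not in ("cvr", "task"):
            raise ConfigurationError(f"unknown run_type {self.run_type!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def volume_midpoints(self) -> np.ndarray:
        """Acquisition midpoint of each volume, in seconds from run start."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr


@dataclass
class CvrResult:
    """Voxel-wise CVR maps for one run.

    ``cvr`` is in percent signal change per mmHg, ``lag`` in seconds
    (positive = BOLD follows CO2), ``tvalue`` is the regression-slope t.
    ``flagged`` marks voxels whose lag could not be estimated (zero variance)
    or saturated at the search-window boundary; they stay in the map with the
    recorded values so mask accounting stays explicit.
    """

    cvr: np.ndarray
    lag: np.ndarray
    tvalue: np.ndarray
    mask: np.ndarray
    baseline_signal: np.ndarray
    flagged: np.ndarray
    condition: str = "normo"

    @property
    def mean_cvr(self) -> float:
        """Whole-mask mean CVR (the per-run 'whole brain' summary)."""
        return float(np.mean(self.cvr[self.mask]))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": [self.condition],
                "n_voxels": [int(self.mask.sum())],
                "n_flagged": [int(self.flagged.sum())],
                "mean_cvr": [self.mean_cvr],
                "mean_lag_s": [float(np.mean(self.lag[self.mask]))],
                "mean_tvalue": [float(np.mean(self.tvalue[self.mask]))],
            }
        )


@dataclass(frozen=True)
class CvrConfig:
    """Tunable settings of the CVR-mapping stage.

    cutoff_hz
        Low-pass corner frequency.  0.1 Hz keeps the (slow) CO2 step
        response while removing high-frequency noise.
    loess_span
        Loess window as a fraction of run length.
    robust_iters
        Bisquare reweighting iterations of the loess smoother.
    lag_window_s / lag_grid_s
        Half-width and step of the lag search grid, in seconds.
    baseline_seconds
        Initial window used to normalise each voxel to percent signal
        change (the resting clamp period of a CVR run).
    smooth
        If False, skip temporal smoothing entirely.
    """

    cutoff_hz: float = 0.1
    loess_span: float = 0.1
    robust_iters: int = 2
    lag_window_s: float = 10.0
    lag_grid_s: float = 1.0
    baseline_seconds: float = 100.0
    smooth: bool = True


def make_analysis_mask(
    gm_prob: np.ndarray, wm_prob: np.ndarray, threshold: float = 0.8
) -> np.ndarray:
    """Binary analysis mask from tissue probability maps.

    A voxel is analysed if its combined grey + white matter probability
    (capped at 1) reaches ``threshold``.
    """
    gm = np.asarray(gm_prob, dtype=float)
    wm = np.asarray(wm_prob, dtype=float)
    if gm.shape != wm.shape:
        raise DimensionError("gm and wm probability volumes differ in shape")
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError("threshold must lie in (0, 1)")
    if gm.min() < 0 or gm.max() > 1 or wm.min() < 0 or wm.max() > 1:
        raise ConfigurationError("tissue probabilities must lie in [0, 1]")
    return np.minimum(gm + wm, 1.0) >= threshold


def _lowpass(series_2d: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    b, a = sps.butter(4, cutoff_hz / nyquist)
    return sps.filtfilt(b, a, series_2d, axis=-1)

def _loess(series_2d: np.ndarray, span: float, iters: int) -> np.ndarray:
    x = np.arange(series_2d.shape[-1], dtype=float)
    out = np.empty_like(series_2d)
    for i in range(series_2d.shape[0]):
        out[i] = lowess(
            series_2d[i], x, frac=span, it=iters, return_sorted=False
        )
    return out


def _smooth_many(series_2d: np.ndarray, tr: float, config: CvrConfig) -> np.ndarray:
    """Low-pass + robust loess along the last axis of a (series, time) array.

    The composite operator is affine-equivariant: smoothing ``a + b*x(t)``
    gives ``a + b*smooth(x)(t)``, which is what keeps the CVR slope unbiased
    when the same operator is applied to BOLD and regressor.
    """
    if not config.smooth:
        return np.array(series_2d, dtype=float, copy=True)
    out = _lowpass(np.asarray(series_2d, dtype=float), tr, config.cutoff_hz)
    return _loess(out, config.loess_span, config.robust_iters)


def temporal_smooth(
    series: np.ndarray,
    tr: float,
    cutoff_hz: float = 0.1,
    loess_span: float = 0.1,
    robust_iters: int = 2,
) -> np.ndarray:
    """Smooth one time series: zero-phase Butterworth low-pass, then robust
    locally weighted regression (loess) with bisquare reweighting.

    Output has the same length as the input; constants and straight lines
    pass through unchanged (away from the filter's edge transients).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 10:
        raise ConfigurationError("series must be 1D with length >= 10")
    cfg = CvrConfig(cutoff_hz=cutoff_hz, loess_span=loess_span, robust_iters=robust_iters)
    return _smooth_many(series[None, :], tr, cfg)[0]


def resample_co2(
    trace: Co2Trace, n_timepoints: int, tr: float, shift_s: float = 0.0
) -> np.ndarray:
    """Linearly interpolate a CO2 trace at volume acquisition midpoints.

    ``shift_s`` evaluates the trace at ``t - shift_s`` (used for lag
    alignment; the trace is extended by its edge values there, matching a
    clamp held before/after the scan).  With ``shift_s = 0`` the trace must
    span the run to within one TR; otherwise a :class:`CoverageError` is
    raised — no silent extrapolation.
    """
    if n_timepoints < 1:
        raise ConfigurationError("n_timepoints must be positive")
    mid = (np.arange(n_timepoints) + 0.5) * tr
    if shift_s == 0.0:
        if trace.time[0] > mid[0] + tr or trace.time[-1] < mid[-1] - tr:
            raise CoverageError(
                f"trace [{trace.time[0]}, {trace.time[-1]}] s does not cover "
                f"run midpoints [{mid[0]}, {mid[-1]}] s within one TR"
            )
    return np.interp(mid - shift_s, trace.time, trace.petco2)


def _tie_break_order(lags: np.ndarray) -> np.ndarray:
    """Candidate order: smallest |lag| first, negative before positive."""
    return np.array(sorted(range(lags.size), key=lambda i: (abs(lags[i]), lags[i])))


def estimate_lag(
    voxel_pct: np.ndarray,
    regressor: np.ndarray,
    tr: float,
    window_s: float = 10.0,
    grid_s: float = 1.0,
) -> tuple[float, bool]:
    """Hemodynamic lag of one voxel by cross-correlation.

    Returns ``(lag_seconds, flagged)``.  The lag maximising the Pearson
    correlation between the voxel series and the regressor shifted by each
    candidate lag is returned; candidate lags run over
    ``[-window_s, window_s]`` in steps of ``grid_s``.  Ties are broken
    toward the smallest ``|lag|`` and then toward the negative lag.  A
    zero-variance series cannot be lagged: lag 0 is recorded and the voxel
    flagged.  A lag at the window boundary is flagged as saturated.
    """
    y = np.asarray(voxel_pct, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DimensionError("voxel and regressor must be 1D of equal length")
    n = y.size
    if window_s > n * tr / 4:
        raise ConfigurationError("lag window exceeds a quarter of the run duration")
    lags = np.arange(-window_s, window_s + grid_s / 2, grid_s)
    if y.std() == 0 or x.std() == 0:
        return 0.0, True
    mid = (np.arange(n) + 0.5) * tr
    corrs = np.empty(lags.size)
    yc = (y - y.mean()) / y.std()
    for i, lag in enumerate(lags):
        xs = np.interp(mid - lag, mid, x)
        sd = xs.std()
        corrs[i] = 0.0 if sd == 0 else np.dot(yc, (xs - xs.mean()) / sd) / n
    order = _tie_break_order(lags)
    best = corrs.max()
    idx = order[np.argmax(corrs[order] >= best - 1e-12)]
    lag = float(lags[idx])
    return lag, bool(abs(lag) >= window_s)


def _ols_slope_t(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and t of a simple OLS fit with intercept; t capped at T_CAP."""
    n = y.size
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise DegenerateRegressionError("regressor has zero variance")
    slope = float(np.dot(xc, y)) / sxx
    resid = y - y.mean() - slope * xc
    rss = float(np.dot(resid, resid))
    dof = n - 2
    if rss <= 0 or dof <= 0:
        t = np.sign(slope) * T_CAP if slope != 0 else 0.0
    else:
        se = np.sqrt(rss / dof / sxx)
        t = slope / se
        t = float(np.clip(t, -T_CAP, T_CAP))
    return slope, t


def fit_voxel_cvr(
    voxel: np.ndarray,
    regressor: np.ndarray,
    lag: float,
    baseline_window: slice,
    tr: float = 2.0,
) -> tuple[float, float, float]:
    """Fit CVR for a single voxel: returns ``(cvr, tvalue, baseline)``.

    The raw voxel series is converted to percent change about its
    baseline-window mean, the regressor is shifted by ``lag`` seconds
    (positive lag delays the regressor), and percent signal is regressed on
    the shifted regressor by ordinary least squares with an intercept.  The
    slope is CVR in %/mmHg, ``tvalue`` its t statistic (capped at
    ``T_CAP`` for noise-free data).
    """
    y = np.asarray(voxel, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DimensionError("voxel and regressor must be 1D of equal length")
    base = y[baseline_window]
    if base.size == 0:
        raise ConfigurationError("baseline window is empty")
    baseline = float(base.mean())
    if baseline <= 0:
        raise ZeroBaselineError("baseline-window mean is not positive")
    pct = 100.0 * (y / baseline - 1.0)
    if lag != 0.0:
        mid = (np.arange(y.size) + 0.5) * tr
        x = np.interp(mid - lag, mid, x)
    if pct.std() == 0:
        return 0.0, 0.0, baseline
    slope, t = _ols_slope_t(pct, x)
    return slope, t, baseline


def compute_cvr_map(
    run: BoldRun,
    trace: Co2Trace,
    mask: np.ndarray,
    config: CvrConfig | None = None,
) -> CvrResult:
    """Full voxel-wise CVR mapping of one run.

    Per masked voxel: percent normalisation about the baseline window,
    temporal smoothing, lag estimation against shift-resampled (and
    identically smoothed) copies of the CO2 regressor, then OLS of percent
    signal on the lag-aligned regressor.  Voxels with a non-positive
    baseline mean are dropped from the output mask; zero-variance and
    lag-saturated voxels stay in the map but are flagged.
    """
    if config is None:
        config = CvrConfig()
    if run.run_type != "cvr":
        raise ConfigurationError("compute_cvr_map expects a CVR run")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise DimensionError("mask shape does not match run volume shape")
    n_t = run.n_volumes
    n_base = max(1, int(round(config.baseline_seconds / run.tr)))
    if n_base > n_t:
        raise ConfigurationError("baseline window longer than the run")

    vox = run.data[mask]  # (V, T)
    baseline = vox[:, :n_base].mean(axis=1)
    good = baseline > 0
    out_mask = np.zeros_like(mask)
    out_mask[mask] = good
    vox = vox[good]
    baseline = baseline[good]
    pct = 100.0 * (vox / baseline[:, None] - 1.0)
    pct_s = _smooth_many(pct, run.tr, config)

    # candidate regressors: trace shift-resampled at each lag, then smoothed
    # with the same operator as the BOLD data
    resample_co2(trace, n_t, run.tr)  # coverage check at zero shift
    lags = np.arange(
        -config.lag_window_s,
        config.lag_window_s + config.lag_grid_s / 2,
        config.lag_grid_s,
    )
    regs = np.stack(
        [resample_co2(trace, n_t, run.tr, shift_s=lag) for lag in lags]
    )
    regs_s = _smooth_many(regs, run.tr, config)

    # cross-correlation of every voxel against every candidate, vectorised
    v_sd = pct_s.std(axis=1)
    r_sd = regs_s.std(axis=1)
    if np.any(r_sd == 0):
        raise DegenerateRegressionError("CO2 regressor has zero variance")
    flat = v_sd == 0
    v_sd_safe = np.where(flat, 1.0, v_sd)
    zv = (pct_s - pct_s.mean(axis=1, keepdims=True)) / v_sd_safe[:, None]
    zr = (regs_s - regs_s.mean(axis=1, keepdims=True)) / r_sd[:, None]
    corr = zv @ zr.T / n_t  # (V, L)

    order = _tie_break_order(lags)
    best = corr.max(axis=1)
    pick = order[np.argmax(corr[:, order] >= best[:, None] - 1e-12, axis=1)]
    pick[flat] = int(np.argmin(np.abs(lags)))  # lag 0 for flat voxels
    lag_v = lags[pick]
    flag_v = flat | (np.abs(lag_v) >= config.lag_window_s)

    # OLS per lag group (all voxels sharing a lag share the regressor)
    cvr_v = np.zeros(pct_s.shape[0])
    t_v = np.zeros(pct_s.shape[0])
    dof = n_t - 2
    for li in np.unique(pick):
        sel = pick == li
        x = regs_s[li]
        xc = x - x.mean()
        sxx = float(np.dot(xc, xc))
        yg = pct_s[sel]
        slopes = yg @ xc / sxx
        resid = yg - yg.mean(axis=1, keepdims=True) - slopes[:, None] * xc
        rss = np.einsum("ij,ij->i", resid, resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / dof / sxx)
            t = np.where(se > 0, slopes / se, np.sign(slopes) * T_CAP)
        cvr_v[sel] = slopes
        t_v[sel] = np.clip(t, -T_CAP, T_CAP)
    cvr_v[flat] = 0.0
    t_v[flat] = 0.0

    shape = run.data.shape[:3]
    out = CvrResult(
        cvr=_embed(cvr_v, out_mask, shape),
        lag=_embed(lag_v, out_mask, shape),
        tvalue=_embed(t_v, out_mask, shape),
        mask=out_mask,
        baseline_signal=_embed(baseline, out_mask, shape),
        flagged=_embed(flag_v, out_mask, shape).astype(bool),
        condition=run.condition,
    )
    return out


def _embed(values: np.ndarray, mask: np.ndarray, shape) -> np.ndarray:
    vol = np.zeros(shape, dtype=values.dtype if values.dtype != bool else bool)
    vol[mask] = values
    return vol
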