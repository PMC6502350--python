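"""Synthetic two-condition BOLD phantom cohorts with known ground truth.

The generator emulates a combined CVR + task-fMRI session: a CVR run
acquired during a pseudo-square ~+10 mmHg end-tidal CO2 step (after a 100 s
resting clamp), and a block-design finger-tapping run acquired at a clamped
CO2 baseline — each once at the subject's resting CO2 ("normo") and once at
a ~+6 mmHg hypercapnic baseline ("hyper").  Hypercapnia reduces the
remaining vasodilatory reserve, which the phantom encodes as
condition-specific ground-truth CVR slopes and task response amplitudes
(the hyper truths are roughly half the normo truths, the saturation effect
the analysis is designed to detect).

Every voxel's true CVR (%/mmHg), hemodynamic lag (s) and task percent
signal change are known, so every downstream estimate can be verified by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvr import BoldRun, Co2Trace
from .errors import ConfigurationError, ProtocolError
from .glm import HrfSpec, Paradigm, hrf_convolved_regressor

__all__ = [
    "REGIONS",
    "ProtocolSpec",
    "SubjectSpec",
    "Phantom",
    "default_region_truth",
    "make_co2_trace",
    "make_task_paradigm",
    "make_phantom",
    "simulate_cvr_run",
    "simulate_task_run",
]

#: the nine motor-network regions represented in the phantom
REGIONS = (
    "precentral_right",
    "precentral_left",
    "postcentral_right",
    "postcentral_left",
    "frontal_operculum_right",
    "frontal_operculum_left",
    "cerebellum_right",
    "cerebellum_left",
    "sma",
)

# per-artifact RNG stream ids (mixed with the subject seed so the phantom
# geometry and each simulated run draw from independent, reproducible
# streams)
_STREAMS = {
    "phantom": 0,
    ("cvr", "normo"): 1,
    ("cvr", "hyper"): 2,
    ("task", "normo"): 3,
    ("task", "hyper"): 4,
}


def _rng(seed: int, stream) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), _STREAMS[stream]]))
    )


def default_region_truth() -> pd.DataFrame:
    """Ground-truth table for a healthy motor network.

    Columns: true CVR slope (%/mmHg) and true task percent signal change,
    each under the normocapnic and hypercapnic baselines.  Values are
    representative group means for healthy adults; the hypercapnic column
    carries the ~50% CVR reduction produced by exhausting part of the
    vasodilatory reserve.
    """
    rows = {
        #                         cvr_n  cvr_h  dpct_n dpct_h
        "precentral_right":      (0.22, 0.11, 0.85, 0.56),
        "precentral_left":       (0.21, 0.10, 0.84, 0.53),
        "postcentral_right":     (0.24, 0.13, 0.87, 0.60),
        "postcentral_left":      (0.26, 0.13, 0.87, 0.59),
        "frontal_operculum_right": (0.29, 0.11, 0.50, 0.29),
        "frontal_operculum_left":  (0.34, 0.14, 0.54, 0.33),
        "cerebellum_right":      (0.29, 0.16, 0.70, 0.43),
        "cerebellum_left":       (0.28, 0.16, 0.63, 0.30),
        "sma":                   (0.24, 0.10, 0.55, 0.41),
    }
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["true_cvr_normo", "true_cvr_hyper", "true_dpct_normo", "true_dpct_hyper"],
    ).rename_axis("region")


@dataclass(frozen=True)
class ProtocolSpec:
    """Scan-protocol timing for one combined CVR + task session."""

    tr_seconds: float = 2.0
    n_volumes_cvr: int = 200
    n_volumes_task: int = 135
    clamp_seconds: float = 100.0
    step_seconds: float = 80.0
    step_mmHg: float = 10.0
    hypercapnic_offset_mmHg: float = 6.0
    task_block_seconds: float = 30.0
    n_task_blocks: int = 4
    ramp_seconds: float = 6.0

    def __post_init__(self):
        if self.tr_seconds <= 0 or self.step_seconds <= 0:
            raise ProtocolError("tr and step duration must be positive")
        if self.n_volumes_cvr <= 0 or self.n_volumes_task <= 0:
            raise ProtocolError("volume counts must be positive")
        if self.clamp_seconds < 0 or self.ramp_seconds < 0:
            raise ProtocolError("clamp and ramp durations must be non-negative")
        if self.task_block_seconds <= 0 or self.n_task_blocks < 0:
            raise ProtocolError("task blocks must have positive duration")
        if (
            self.clamp_seconds + 2 * self.ramp_seconds + self.step_seconds
            >= self.cvr_duration
        ):
            raise ProtocolError("CO2 stimulus does not fit inside the CVR run")
        if (
            self.n_task_blocks * 2 * self.task_block_seconds
            > self.task_duration
        ):
            raise ProtocolError("task blocks do not fit inside the task run")

    @property
    def cvr_duration(self) -> float:
        return self.n_volumes_cvr * self.tr_seconds

    @property
    def task_duration(self) -> float:
        return self.n_volumes_task * self.tr_seconds


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject simulation settings and embedded ground truth.

    ``region_truth`` must be indexed by exactly the nine :data:`REGIONS`
    names with the four truth columns of :func:`default_region_truth`.
    ``noise_sd_pct`` is the thermal-noise standard deviation as a percent
    of baseline signal; ``drift_amplitude_pct`` scales a slow order-2
    Legendre drift (0 disables it).
    """

    subject_id: str = "sub-01"
    resting_petco2_mmHg: float = 38.0
    region_truth: pd.DataFrame = field(default_factory=default_region_truth)
    lag_range_seconds: tuple = (0.0, 8.0)
    noise_sd_pct: float = 1.0
    drift_amplitude_pct: float = 0.0
    drift_order: int = 2
    baseline_signal: float = 800.0
    seed: int = 0

    def __post_init__(self):
        truth = self.region_truth
        required = {"true_cvr_normo", "true_cvr_hyper", "true_dpct_normo", "true_dpct_hyper"}
        if set(truth.index) != set(REGIONS) or not required <= set(truth.columns):
            raise ConfigurationError(
                "region_truth must cover exactly the nine motor-network regions "
                "with the four truth columns"
            )
        if (truth[["true_cvr_normo", "true_cvr_hyper"]] < 0).any().any():
            raise ConfigurationError("true CVR values must be non-negative")
        if self.noise_sd_pct < 0:
            raise ConfigurationError("noise sd must be non-negative")
        if self.drift_amplitude_pct < 0:
            raise ConfigurationError("drift amplitude must be non-negative")
        lo, hi = self.lag_range_seconds
        if lo > hi:
            raise ConfigurationError("lag_range_seconds must be ordered (lo, hi)")


@dataclass
class Phantom:
    """Digital subject: region labels, tissue probabilities and truth maps.

    ``truth_cvr`` and ``truth_dpct`` map condition name -> 3D volume
    (constant within each region, zero in background); ``truth_lag`` is the
    shared per-voxel hemodynamic lag in seconds, quantised to the CO2
    sampling grid.
    """

    grid_shape: tuple
    labels: np.ndarray
    names: dict
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    truth_cvr: dict
    truth_dpct: dict
    truth_lag: np.ndarray
    spec: SubjectSpec

    def region_mask(self, region: str) -> np.ndarray:
        label = {v: k for k, v in self.names.items()}[region]
        return self.labels == label


def make_co2_trace(
    protocol: ProtocolSpec,
    condition: str,
    resting_petco2: float = 38.0,
) -> Co2Trace:
    """Simulated end-tidal CO2 trace for a CVR run, sampled at 1 s.

    Baseline (resting PetCO2, plus the hypercapnic offset under "hyper")
    for the clamp period, a linear ramp up over ``protocol.ramp_seconds``,
    a plateau of ``step_mmHg`` above baseline held for ``step_seconds``, a
    ramp back down, then baseline until the end of the run.
    """
    if condition not in ("normo", "hyper"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    base = resting_petco2 + (
        protocol.hypercapnic_offset_mmHg if condition == "hyper" else 0.0
    )
    t = np.arange(0.0, protocol.cvr_duration + 0.5, 1.0)
    pet = np.full_like(t, base)
    up0 = protocol.clamp_seconds
    up1 = up0 + protocol.ramp_seconds
    dn0 = up1 + protocol.step_seconds
    dn1 = dn0 + protocol.ramp_seconds
    step = protocol.step_mmHg
    if protocol.ramp_seconds > 0:
        rising = (t > up0) & (t < up1)
        pet[rising] = base + step * (t[rising] - up0) / protocol.ramp_seconds
        falling = (t > dn0) & (t < dn1)
        pet[falling] = base + step * (1 - (t[falling] - dn0) / protocol.ramp_seconds)
    pet[(t >= up1) & (t <= dn0)] = base + step
    return Co2Trace(t, pet)


def make_task_paradigm(
    protocol: ProtocolSpec,
    condition_baseline: float,
    jitter_sd_mmHg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Paradigm, Co2Trace]:
    """Block paradigm plus the clamped CO2 trace of a task run.

    Blocks of ``task_block_seconds`` alternate with equal rest periods,
    starting with rest, so the default protocol yields onsets at 30, 90,
    150 and 210 s.  The CO2 trace is constant at ``condition_baseline``
    (optionally with small Gaussian jitter, emulating clamp imprecision).
    """
    block = protocol.task_block_seconds
    onsets = tuple((2 * k + 1) * block for k in range(protocol.n_task_blocks))
    durations = (block,) * protocol.n_task_blocks
    if onsets and onsets[-1] + block > protocol.task_duration:
        raise ProtocolError("task blocks exceed the run length")
    paradigm = Paradigm(onsets, durations, label="finger_tapping")
    t = np.arange(0.0, protocol.task_duration + 0.5, 1.0)
    pet = np.full_like(t, condition_baseline)
    if jitter_sd_mmHg > 0:
        if rng is None:
            rng = np.random.default_rng()
        pet = pet + rng.normal(0.0, jitter_sd_mmHg, t.shape)
    return paradigm, Co2Trace(t, pet)


def _region_slabs(grid_shape: tuple) -> list[tuple]:
    """Nine equal block-shaped regions in a 3x3 in-plane arrangement."""
    nx, ny, nz = grid_shape
    wx = (nx - 6) // 3
    wy = (ny - 6) // 3
    z0, z1 = nz // 4, nz - nz // 4
    if wx < 1 or wy < 1 or z1 - z0 < 1:
        raise ConfigurationError(
            f"grid {grid_shape} too small for nine non-empty regions"
        )
    xs = [1, 1 + wx + 2, 1 + 2 * (wx + 2)]
    ys = [1, 1 + wy + 2, 1 + 2 * (wy + 2)]
    slabs = []
    for gy in ys:
        for gx in xs:
            slabs.append((slice(gx, gx + wx), slice(gy, gy + wy), slice(z0, z1)))
    return slabs


def make_phantom(spec: SubjectSpec, grid_shape: tuple = (24, 24, 12)) -> Phantom:
    """Build the digital subject: labels, tissue probabilities, truth maps.

    Region geometry is a deterministic 3x3 arrangement of equal blocks;
    per-voxel lags are drawn uniformly from ``spec.lag_range_seconds`` and
    quantised to the 1 s CO2 sampling grid so exact lag recovery is a
    testable property.
    """
    slabs = _region_slabs(grid_shape)
    labels = np.zeros(grid_shape, dtype=np.int16)
    for i, slab in enumerate(slabs, start=1):
        labels[slab] = i
    names = {i + 1: r for i, r in enumerate(REGIONS)}

    in_region = labels > 0
    gm = np.where(in_region, 0.70, 0.02)
    wm = np.where(in_region, 0.28, 0.02)

    truth = spec.region_truth
    truth_cvr = {}
    truth_dpct = {}
    for cond in ("normo", "hyper"):
        cvr_vol = np.zeros(grid_shape)
        dpct_vol = np.zeros(grid_shape)
        for lab, region in names.items():
            cvr_vol[labels == lab] = truth.loc[region, f"true_cvr_{cond}"]
            dpct_vol[labels == lab] = truth.loc[region, f"true_dpct_{cond}"]
        truth_cvr[cond] = cvr_vol
        truth_dpct[cond] = dpct_vol

    rng = _rng(spec.seed, "phantom")
    lo, hi = spec.lag_range_seconds
    lag = rng.uniform(lo, hi, size=grid_shape)
    lag = np.round(lag)  # CO2 trace is sampled at 1 s
    lag[~in_region] = 0.0

    return Phantom(
        grid_shape=tuple(grid_shape),
        labels=labels,
        names=names,
        gm_prob=gm,
        wm_prob=wm,
        truth_cvr=truth_cvr,
        truth_dpct=truth_dpct,
        truth_lag=lag,
        spec=spec,
    )


def _drift(
    rng: np.random.Generator,
    n_voxels: int,
    n_t: int,
    amplitude_pct: float,
    order: int,
) -> np.ndarray:
    """Slow per-voxel Legendre drift as a fraction of baseline signal."""
    if amplitude_pct == 0 or order == 0:
        return np.zeros((n_voxels, n_t))
    from numpy.polynomial import legendre

    x = np.linspace(-1.0, 1.0, n_t)
    basis = np.stack([legendre.Legendre.basis(k)(x) for k in range(1, order + 1)])
    coef = rng.uniform(-1.0, 1.0, size=(n_voxels, order))
    return (amplitude_pct / 100.0) * (coef @ basis) / order


def simulate_cvr_run(
    phantom: Phantom,
    trace: Co2Trace,
    spec: SubjectSpec,
    protocol: ProtocolSpec,
    condition: str = "normo",
) -> BoldRun:
    """Simulate a CVR run from the phantom's ground truth.

    Each voxel follows ``S0 * (1 + cvr/100 * (CO2(t - lag) - baseline))``
    plus optional slow drift and white Gaussian noise (sd =
    ``noise_sd_pct`` percent of S0).  CO2 is evaluated at volume
    acquisition midpoints; before the trace starts it is held at its first
    (clamped) value.
    """
    if condition not in ("normo", "hyper"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if abs(trace.duration - protocol.cvr_duration) > protocol.tr_seconds:
        raise ProtocolError("trace duration does not match the CVR protocol")
    n_t = protocol.n_volumes_cvr
    tr = protocol.tr_seconds
    mid = (np.arange(n_t) + 0.5) * tr
    base_co2 = float(trace.petco2[0])
    s0 = spec.baseline_signal

    cvr = phantom.truth_cvr[condition].ravel()
    lag = phantom.truth_lag.ravel()
    n_vox = cvr.size
    sig = np.empty((n_vox, n_t))
    for lag_val in np.unique(lag):
        co2 = np.interp(mid - lag_val, trace.time, trace.petco2)
        rows = lag == lag_val
        sig[rows] = s0 * (1.0 + np.outer(cvr[rows] / 100.0, co2 - base_co2))

    rng = _rng(spec.seed, ("cvr", condition))
    sig += s0 * _drift(rng, n_vox, n_t, spec.drift_amplitude_pct, spec.drift_order)
    if spec.noise_sd_pct > 0:
        sig += rng.normal(0.0, spec.noise_sd_pct / 100.0 * s0, size=sig.shape)
    data = sig.reshape(*phantom.grid_shape, n_t)
    return BoldRun(data, tr=tr, condition=condition, run_type="cvr")


def simulate_task_run(
    phantom: Phantom,
    paradigm: Paradigm,
    spec: SubjectSpec,
    protocol: ProtocolSpec,
    condition: str = "normo",
    hrf: HrfSpec | None = None,
) -> BoldRun:
    """Simulate a block-design task run.

    Each voxel follows ``S0 * (1 + dpct/100 * r(t))`` with ``r`` the
    unit-peak HRF-convolved block regressor (the same regressor the GLM
    stage fits), plus optional drift and Gaussian noise.
    """
    if condition not in ("normo", "hyper"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if hrf is None:
        hrf = HrfSpec()
    n_t = protocol.n_volumes_task
    reg = hrf_convolved_regressor(paradigm, hrf, n_t, protocol.tr_seconds)
    dpct = phantom.truth_dpct[condition].ravel()
    s0 = spec.baseline_signal
    sig = s0 * (1.0 + np.outer(dpct / 100.0, reg))

    rng = _rng(spec.seed, ("task", condition))
    sig += s0 * _drift(
        rng, dpct.size, n_t, spec.drift_amplitude_pct, spec.drift_order
    )
    if spec.noise_sd_pct > 0:
        sig += rng.normal(0.0, spec.noise_sd_pct / 100.0 * s0, size=sig.shape)
    data = sig.reshape(*phantom.grid_shape, n_t)
    return BoldRun(data, tr=protocol.tr_seconds, condition=condition, run_type="task")
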