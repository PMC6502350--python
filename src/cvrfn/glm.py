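"""Task-evoked activation analysis: design matrices, mass-univariate GLM,
t-thresholded activation masks and percent-signal-change (dpct) maps.

The task regressor is the block paradigm convolved with a canonical
double-gamma hemodynamic response function and scaled to unit peak, so the
regression coefficient on percent-normalised signal reads directly as the
task-evoked percent BOLD signal change (dpct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.stats import gamma as gamma_dist

from .cvr import BoldRun, T_CAP
from .errors import (
    CollinearityError,
    ConfigurationError,
    DimensionError,
    ProtocolError,
)

__all__ = [
    "Paradigm",
    "HrfSpec",
    "ActivationResult",
    "hrf_convolved_regressor",
    "build_design",
    "fit_task_glm",
    "threshold_tmap",
    "combined_sig_mask",
    "DEFAULT_T_THRESHOLD",
]

#: default voxel-level significance threshold on the task t-map
DEFAULT_T_THRESHOLD = 3.43


@dataclass(frozen=True)
class Paradigm:
    """Block-design task timing: per-block onset and duration in seconds."""

    onsets: tuple
    durations: tuple
    label: str = "task"

    def __post_init__(self):
        onsets = tuple(float(o) for o in self.onsets)
        durations = tuple(float(d) for d in self.durations)
        if len(onsets) != len(durations):
            raise ProtocolError("onsets and durations differ in length")
        if any(d <= 0 for d in durations):
            raise ProtocolError("block durations must be positive")
        if list(onsets) != sorted(onsets):
            raise ProtocolError("onsets must be sorted")
        for (o1, d1), o2 in zip(zip(onsets, durations), onsets[1:]):
            if o1 + d1 > o2:
                raise ProtocolError("task blocks overlap")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)

    @property
    def n_blocks(self) -> int:
        return len(self.onsets)

    def to_csv(self, path):
        pd.DataFrame(
            {
                "onset_s": self.onsets,
                "duration_s": self.durations,
                "condition": [self.label] * self.n_blocks,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Paradigm":
        df = pd.read_csv(path)
        label = str(df["condition"].iloc[0]) if len(df) else "task"
        return cls(
            tuple(df["onset_s"]), tuple(df["duration_s"]), label=label
        )


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma hemodynamic response function.

    Defaults: response peaking at 6 s, undershoot peaking at 16 s, unit
    dispersions, undershoot weight 1/6.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self):
        if min(
            self.peak_delay,
            self.undershoot_delay,
            self.peak_dispersion,
            self.undershoot_dispersion,
            self.undershoot_ratio,
        ) <= 0:
            raise ConfigurationError("all HRF parameters must be positive")

    def sample(self, t: np.ndarray) -> np.ndarray:
        """HRF values at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        peak = gamma_dist.pdf(
            t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion
        )
        under = gamma_dist.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        h = peak - self.undershoot_ratio * under
        if np.trapezoid(h, t) <= 0:
            raise ConfigurationError("HRF does not integrate to a positive value")
        return h


@dataclass
class ActivationResult:
    """Task GLM output: t-map, dpct (percent signal change) map, and — once
    thresholded — the binary significance mask."""

    tvalue: np.ndarray
    dpct: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray
    sig_mask: np.ndarray | None = None
    threshold: float | None = None
    n_nuisance: int = 0
    condition: str = "normo"

    def summary(self) -> pd.DataFrame:
        row = {
            "condition": [self.condition],
            "n_voxels": [int(self.mask.sum())],
            "n_flagged": [int(self.flagged.sum())],
            "mean_dpct": [float(np.mean(self.dpct[self.mask]))],
            "mean_tvalue": [float(np.mean(self.tvalue[self.mask]))],
        }
        if self.sig_mask is not None:
            row["threshold"] = [self.threshold]
            row["n_significant"] = [int(self.sig_mask.sum())]
        return pd.DataFrame(row)


def hrf_convolved_regressor(
    paradigm: Paradigm,
    hrf: HrfSpec,
    n_timepoints: int,
    tr: float,
    dt: float = 0.1,
) -> np.ndarray:
    """Unit-peak task regressor at volume acquisition midpoints.

    The block boxcar is built at ``dt`` resolution, convolved with the HRF,
    sampled at volume midpoints and divided by its maximum, so a regression
    coefficient on percent signal is the task percent signal change at the
    response plateau.  An empty paradigm yields an all-zero regressor (a
    warning is emitted).
    """
    run_len = n_timepoints * tr
    for o, d in zip(paradigm.onsets, paradigm.durations):
        if o < 0 or o + d > run_len:
            raise ProtocolError(
                f"block at {o} s (+{d} s) falls outside the {run_len} s run"
            )
    if paradigm.n_blocks == 0:
        warnings.warn("empty paradigm: returning a zero regressor", stacklevel=2)
        return np.zeros(n_timepoints)
    fine_t = np.arange(0.0, run_len, dt)
    box = np.zeros_like(fine_t)
    for o, d in zip(paradigm.onsets, paradigm.durations):
        box[(fine_t >= o) & (fine_t < o + d)] = 1.0
    kernel = hrf.sample(np.arange(0.0, hrf.duration + dt / 2, dt))
    conv = np.convolve(box, kernel)[: fine_t.size] * dt
    mid = (np.arange(n_timepoints) + 0.5) * tr
    reg = np.interp(mid, fine_t, conv)
    peak = reg.max()
    if peak <= 0:
        warnings.warn("paradigm produced a non-positive regressor", stacklevel=2)
        return np.zeros(n_timepoints)
    return reg / peak


def drift_columns(n_timepoints: int, order: int) -> np.ndarray:
    """Legendre polynomial drift regressors P1..P_order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_timepoints)
    return np.column_stack(
        [legendre.Legendre.basis(k)(x) for k in range(1, order + 1)]
    ) if order > 0 else np.empty((n_timepoints, 0))


def build_design(
    regressor: np.ndarray,
    nuisance: np.ndarray | None = None,
    drift_order: int = 0,
) -> pd.DataFrame:
    """Assemble the GLM design matrix as a named-column DataFrame.

    Columns: task regressor, nuisance covariates (e.g. motion parameters),
    Legendre drift terms, intercept.  The matrix rank is stored in
    ``.attrs['rank']``; rank deficiency raises :class:`CollinearityError`
    naming the redundant columns.
    """
    reg = np.asarray(regressor, dtype=float)
    if reg.ndim != 1:
        raise DimensionError("task regressor must be 1D")
    n = reg.size
    cols: list[np.ndarray] = [reg]
    names = ["task"]
    if nuisance is not None:
        nui = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nui.shape[0] != n:
            nui = nui.T
        if nui.shape[0] != n:
            raise DimensionError("nuisance rows do not match regressor length")
        for j in range(nui.shape[1]):
            cols.append(nui[:, j])
            names.append(f"nuisance_{j}")
    dr = drift_columns(n, drift_order)
    for j in range(dr.shape[1]):
        cols.append(dr[:, j])
        names.append(f"drift_{j + 1}")
    cols.append(np.ones(n))
    names.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        redundant = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                redundant.append(names[j])
        raise CollinearityError(redundant)
    df = pd.DataFrame(X, columns=names)
    df.attrs["rank"] = int(rank)
    return df


def fit_task_glm(
    run: BoldRun,
    design: pd.DataFrame,
    mask: np.ndarray,
    baseline_window: slice,
) -> ActivationResult:
    """Mass-univariate GLM of a task run.

    Each masked voxel is normalised to percent change about its
    baseline-window mean (the initial rest block) and regressed on the
    design.  ``dpct`` is the task-column coefficient, ``tvalue`` its t
    statistic.  Voxels with zero variance or a non-positive baseline get
    dpct 0, t 0 and are flagged.
    """
    X = np.asarray(design, dtype=float)
    if X.shape[0] != run.n_volumes:
        raise DimensionError(
            f"design has {X.shape[0]} rows but run has {run.n_volumes} volumes"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise DimensionError("mask shape does not match run volume shape")
    names = list(design.columns)
    task_col = names.index("task")
    n_nuisance = sum(1 for c in names if c.startswith("nuisance_"))

    vox = run.data[mask]  # (V, T)
    base = vox[:, baseline_window].mean(axis=1)
    bad = base <= 0
    base_safe = np.where(bad, 1.0, base)
    pct = 100.0 * (vox / base_safe[:, None] - 1.0)
    flat = pct.std(axis=1) == 0

    xtx_inv = np.linalg.inv(X.T @ X)
    betas = pct @ (xtx_inv @ X.T).T  # (V, p)
    resid = pct - betas @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ConfigurationError("design leaves no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * xtx_inv[task_col, task_col])
        dpct_v = betas[:, task_col]
        t_v = np.where(se > 0, dpct_v / se, np.sign(dpct_v) * T_CAP)
    t_v = np.clip(t_v, -T_CAP, T_CAP)
    flag_v = flat | bad
    dpct_v = np.where(flag_v, 0.0, dpct_v)
    t_v = np.where(flag_v, 0.0, t_v)

    shape = run.data.shape[:3]

    def embed(v, dtype=float):
        vol = np.zeros(shape, dtype=dtype)
        vol[mask] = v
        return vol

    return ActivationResult(
        tvalue=embed(t_v),
        dpct=embed(dpct_v),
        mask=mask.copy(),
        flagged=embed(flag_v, bool),
        n_nuisance=n_nuisance,
        condition=run.condition,
    )


def threshold_tmap(
    result: ActivationResult, threshold: float = DEFAULT_T_THRESHOLD
) -> ActivationResult:
    """Attach the binary significance mask: voxels with t strictly greater
    than ``threshold`` (within the analysis mask)."""
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    sig = (result.tvalue > threshold) & result.mask
    return replace(result, sig_mask=sig, threshold=float(threshold))


def combined_sig_mask(mask_normo: np.ndarray, mask_hyper: np.ndarray) -> np.ndarray:
    """Voxels significant in at least one of the two conditions (union)."""
    a = np.asarray(mask_normo, dtype=bool)
    b = np.asarray(mask_hyper, dtype=bool)
    if a.shape != b.shape:
        raise DimensionError("significance masks differ in shape")
    return a | b
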