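"""Region-level comparison of CVR and task activation across CO2 conditions.

Builds the per-region summary tables (mean CVR, mean task percent signal
change, mean t, significant-voxel counts), the paired condition tests with
Bonferroni correction, the ROI-mean CVR-vs-activation regressions, and the
voxel-level false-negative analyses: voxels significant under normocapnia
but sub-threshold under hypercapnia, and activated voxels with low task
response despite preserved CVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateRegressionError,
    DimensionError,
    LabelingError,
)

__all__ = [
    "RoiLabelMap",
    "PairedTestResult",
    "RegressionResult",
    "summarize_roi",
    "count_significant",
    "paired_condition_test",
    "repeated_measures_condition_test",
    "regress_cvr_vs_dpct",
    "false_negative_voxels",
    "low_activation_high_cvr",
]


@dataclass(frozen=True)
class RoiLabelMap:
    """Integer label volume plus label -> region-name mapping."""

    labels: np.ndarray
    names: dict

    def __post_init__(self):
        labels = np.asarray(self.labels)
        present = set(np.unique(labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise LabelingError(f"labels without names: {sorted(unnamed)}")
        object.__setattr__(self, "labels", labels)

    @property
    def regions(self) -> dict:
        """region name -> label id"""
        return {v: k for k, v in self.names.items()}

    def mask(self, region: str) -> np.ndarray:
        try:
            label = self.regions[region]
        except KeyError:
            raise LabelingError(f"unknown region {region!r}") from None
        return self.labels == label


@dataclass(frozen=True)
class PairedTestResult:
    region: str
    statistic: float
    raw_p: float
    corrected_p: float
    n_subjects: int
    correction_factor: float
    flagged: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n_points: int


def _check_aligned(*volumes):
    shapes = {np.asarray(v).shape for v in volumes}
    if len(shapes) != 1:
        raise DimensionError(f"volumes are not aligned: shapes {shapes}")


def summarize_roi(
    cvr_result,
    activation_result,
    label_map: RoiLabelMap,
    voxel_set: str = "combined_sig",
    combined_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region summary rows for one subject and condition.

    ``voxel_set`` selects the voxels the means run over: "combined_sig"
    (voxels significant in at least one condition; requires
    ``combined_mask``) or "all_masked" (every analysis-mask voxel in the
    region).  Each region yields one row per modality (cvr, fmri) with the
    mean percent-change measure, mean t, significant-voxel count and voxel
    count; empty selections yield NaN means and are flagged.
    """
    _check_aligned(cvr_result.cvr, activation_result.tvalue, label_map.labels)
    if voxel_set == "combined_sig":
        if combined_mask is None:
            raise ConfigurationError(
                "voxel_set='combined_sig' needs the combined significance mask"
            )
        _check_aligned(label_map.labels, combined_mask)
        select = np.asarray(combined_mask, dtype=bool)
    elif voxel_set == "all_masked":
        select = np.asarray(cvr_result.mask, dtype=bool)
    else:
        raise ConfigurationError(f"unknown voxel_set {voxel_set!r}")
    if activation_result.sig_mask is None:
        raise ConfigurationError("activation result has not been thresholded")

    rows = []
    for label, region in sorted(label_map.names.items()):
        region_vox = label_map.labels == label
        sel = region_vox & select
        n_sel = int(sel.sum())
        n_sig = int((region_vox & activation_result.sig_mask).sum())
        for modality, dvol, tvol in (
            ("cvr", cvr_result.cvr, cvr_result.tvalue),
            ("fmri", activation_result.dpct, activation_result.tvalue),
        ):
            empty = n_sel == 0
            rows.append(
                {
                    "region": region,
                    "condition": activation_result.condition,
                    "modality": modality,
                    "mean_dpct": np.nan if empty else float(dvol[sel].mean()),
                    "mean_tvalue": np.nan if empty else float(tvol[sel].mean()),
                    "n_sig_voxels": n_sig,
                    "n_voxels": n_sel,
                    "flagged": empty,
                }
            )
    return pd.DataFrame(rows)


def count_significant(sig_mask: np.ndarray, label_map: RoiLabelMap) -> pd.Series:
    """Significant-voxel count per region."""
    _check_aligned(sig_mask, label_map.labels)
    sig = np.asarray(sig_mask, dtype=bool)
    counts = {
        region: int((label_map.labels == label).__and__(sig).sum())
        for label, region in sorted(label_map.names.items())
    }
    return pd.Series(counts, name="n_sig_voxels")


def paired_condition_test(
    values_normo,
    values_hyper,
    correction_factor: float = 1.0,
    region: str = "",
) -> PairedTestResult:
    """Two-sided paired t-test across subjects, Bonferroni corrected.

    Degenerate cases: all-zero differences give t 0, p 1; zero-variance
    differences with nonzero mean give an infinite t, p 0 and the result
    is flagged.
    """
    a = np.asarray(values_normo, dtype=float)
    b = np.asarray(values_hyper, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("paired test needs two equal-length samples, n >= 2")
    d = a - b
    n = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    flagged = False
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(mean) * np.inf, 0.0
            flagged = True
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(
        region=region,
        statistic=float(t),
        raw_p=float(p),
        corrected_p=float(min(1.0, p * correction_factor)),
        n_subjects=n,
        correction_factor=float(correction_factor),
        flagged=flagged,
    )


# With two conditions, a one-way repeated-measures ANOVA is equivalent to
# the paired t-test (F = t^2), so the ANOVA interface is an alias.
repeated_measures_condition_test = paired_condition_test


def regress_cvr_vs_dpct(points) -> RegressionResult:
    """Least-squares regression of ROI-mean activation on ROI-mean CVR.

    ``points`` is an iterable of (cvr, activation) pairs — one per subject
    and region.  CVR is the independent variable.  Returns slope,
    intercept, Pearson r and the slope t-test p-value.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ConfigurationError("regression needs >= 3 (cvr, activation) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.std(x) == 0:
        raise DegenerateRegressionError("CVR predictor has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n_points=pts.shape[0],
    )


def false_negative_voxels(
    sig_mask_normo: np.ndarray,
    sig_mask_hyper: np.ndarray,
    label_map: RoiLabelMap | None = None,
):
    """Voxels significant under normocapnia but not under hypercapnia.

    These are the candidate false negatives: responses known to exceed
    threshold under normal reactivity that drop below it when reactivity
    is impaired.  Returns the binary volume, plus per-region counts if a
    label map is given.
    """
    a = np.asarray(sig_mask_normo, dtype=bool)
    b = np.asarray(sig_mask_hyper, dtype=bool)
    _check_aligned(a, b)
    fn = a & ~b
    if label_map is None:
        return fn
    return fn, count_significant(fn, label_map)


def low_activation_high_cvr(
    dpct_map: np.ndarray,
    cvr_map: np.ndarray,
    sig_mask: np.ndarray,
    dpct_lt: float = 1.0,
    cvr_gt: float = 0.15,
) -> np.ndarray:
    """Activated voxels with weak task response despite preserved CVR.

    Selects voxels in ``sig_mask`` whose task percent signal change is
    strictly below ``dpct_lt`` while CVR is strictly above ``cvr_gt`` —
    responses that participate in the task but sit close to the detection
    limit even with intact vascular reserve.
    """
    if not (np.isfinite(dpct_lt) and np.isfinite(cvr_gt)):
        raise ConfigurationError("thresholds must be finite")
    _check_aligned(dpct_map, cvr_map, sig_mask)
    sig = np.asarray(sig_mask, dtype=bool)
    return sig & (np.asarray(dpct_map) < dpct_lt) & (np.asarray(cvr_map) > cvr_gt)
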