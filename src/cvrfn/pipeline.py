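"""Cohort-level orchestration: synth -> cvr -> glm -> roi.

Runs the full two-condition analysis for every synthetic subject, then
assembles the group report: regional summaries (mean +/- sd), whole-brain
CVR per condition, paired condition tests with Bonferroni correction, the
ROI-mean CVR-vs-activation regressions, and the false-negative voxel
summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cvr import CvrConfig, CvrResult, compute_cvr_map, make_analysis_mask
from .errors import ConfigurationError, CvrfnError, DegenerateRegressionError
from .glm import (
    DEFAULT_T_THRESHOLD,
    HrfSpec,
    build_design,
    combined_sig_mask,
    fit_task_glm,
    hrf_convolved_regressor,
    threshold_tmap,
)
from .roi import (
    RoiLabelMap,
    count_significant,
    false_negative_voxels,
    low_activation_high_cvr,
    paired_condition_test,
    regress_cvr_vs_dpct,
    summarize_roi,
)
from .synth import (
    REGIONS,
    Phantom,
    ProtocolSpec,
    SubjectSpec,
    default_region_truth,
    make_co2_trace,
    make_phantom,
    make_task_paradigm,
    simulate_cvr_run,
    simulate_task_run,
)

__all__ = [
    "CohortConfig",
    "CohortReport",
    "subject_seed",
    "run_subject",
    "run_cohort",
    "summarize_group",
]

log = logging.getLogger("cvrfn")

CONDITIONS = ("normo", "hyper")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate and analyse one synthetic cohort."""

    n_subjects: int = 17
    grid_shape: tuple = (24, 24, 12)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    resting_petco2_mmHg: float = 38.0
    noise_sd_pct: float = 1.0
    drift_amplitude_pct: float = 0.0
    lag_range_seconds: tuple = (0.0, 8.0)
    region_truth: pd.DataFrame = field(default_factory=default_region_truth)
    t_threshold: float = DEFAULT_T_THRESHOLD
    dpct_lt: float = 1.0
    cvr_gt: float = 0.15
    mask_prob: float = 0.8
    glm_drift_order: int = 2
    cvr_config: CvrConfig = field(default_factory=CvrConfig)
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name in ("t_threshold", "dpct_lt", "cvr_gt", "mask_prob"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "protocol" in kwargs:
            kwargs["protocol"] = ProtocolSpec(**kwargs["protocol"])
        if "cvr_config" in kwargs:
            kwargs["cvr_config"] = CvrConfig(**kwargs["cvr_config"])
        if "grid_shape" in kwargs:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        if "lag_range_seconds" in kwargs:
            kwargs["lag_range_seconds"] = tuple(kwargs["lag_range_seconds"])
        if "region_truth" in kwargs:
            kwargs["region_truth"] = pd.DataFrame.from_dict(
                kwargs["region_truth"], orient="index"
            ).rename_axis("region")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["protocol"] = dataclasses.asdict(self.protocol)
        data["cvr_config"] = dataclasses.asdict(self.cvr_config)
        data["grid_shape"] = list(self.grid_shape)
        data["lag_range_seconds"] = list(self.lag_range_seconds)
        data["region_truth"] = {
            r: {c: float(v) for c, v in row.items()}
            for r, row in self.region_truth.to_dict(orient="index").items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def subject_seed(master_seed: int, index: int) -> int:
    """Per-subject seed: the first state word of SeedSequence([master, i]).

    Deterministic, documented splitting rule; subjects are mutually
    independent and adding subjects never changes earlier ones.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class SubjectResult:
    subject_id: str
    phantom: Phantom
    cvr: dict
    activation: dict
    combined_mask: np.ndarray
    roi_table: pd.DataFrame
    counts: pd.DataFrame
    false_neg_counts: pd.Series
    low_act_high_cvr_n: int
    whole_brain: pd.DataFrame


@dataclass
class CohortReport:
    config: CohortConfig
    subjects: list
    roi_tables: pd.DataFrame
    group_table: pd.DataFrame
    whole_brain: pd.DataFrame
    whole_brain_group: pd.DataFrame
    counts: pd.DataFrame
    paired_tests: pd.DataFrame
    regressions: pd.DataFrame
    false_negative_summary: pd.DataFrame

    def whole_brain_mean(self, condition: str) -> float:
        rows = self.whole_brain[self.whole_brain.condition == condition]
        return float(rows.mean_cvr.mean())

    @property
    def whole_brain_pooled(self) -> float:
        return float(self.whole_brain.mean_cvr.mean())

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.roi_tables.to_csv(out / "roi_subject_tables.csv", index=False)
        self.group_table.to_csv(out / "roi_group_table.csv", index=False)
        self.whole_brain.to_csv(out / "whole_brain_cvr.csv", index=False)
        self.whole_brain_group.to_csv(out / "whole_brain_group.csv", index=False)
        self.counts.to_csv(out / "significant_voxel_counts.csv", index=False)
        self.paired_tests.to_csv(out / "paired_tests.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)
        self.false_negative_summary.to_csv(
            out / "false_negative_summary.csv", index=False
        )
        summary = {
            "n_subjects": self.config.n_subjects,
            "master_seed": self.config.master_seed,
            "whole_brain_cvr": {
                "normo": self.whole_brain_mean("normo"),
                "hyper": self.whole_brain_mean("hyper"),
                "pooled": self.whole_brain_pooled,
            },
        }
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
        return out


def run_subject(config: CohortConfig, index: int) -> SubjectResult:
    """Simulate and analyse one subject (both CO2 conditions)."""
    sid = f"sub-{index + 1:02d}"
    seed = subject_seed(config.master_seed, index)
    spec = SubjectSpec(
        subject_id=sid,
        resting_petco2_mmHg=config.resting_petco2_mmHg,
        region_truth=config.region_truth,
        lag_range_seconds=config.lag_range_seconds,
        noise_sd_pct=config.noise_sd_pct,
        drift_amplitude_pct=config.drift_amplitude_pct,
        seed=seed,
    )
    protocol = config.protocol
    phantom = make_phantom(spec, config.grid_shape)
    label_map = RoiLabelMap(phantom.labels, phantom.names)
    mask = make_analysis_mask(phantom.gm_prob, phantom.wm_prob, config.mask_prob)

    hrf = HrfSpec()
    n_rest_vols = max(1, int(round(protocol.task_block_seconds / protocol.tr_seconds)))
    cvr_results: dict[str, CvrResult] = {}
    activations = {}
    for cond in CONDITIONS:
        t0 = time.perf_counter()
        try:
            trace = make_co2_trace(protocol, cond, spec.resting_petco2_mmHg)
            run = simulate_cvr_run(phantom, trace, spec, protocol, cond)
            cvr_results[cond] = compute_cvr_map(run, trace, mask, config.cvr_config)

            baseline_co2 = float(trace.petco2[0])
            paradigm, _task_trace = make_task_paradigm(protocol, baseline_co2)
            task_run = simulate_task_run(phantom, paradigm, spec, protocol, cond, hrf)
            reg = hrf_convolved_regressor(
                paradigm, hrf, protocol.n_volumes_task, protocol.tr_seconds
            )
            design = build_design(reg, drift_order=config.glm_drift_order)
            act = fit_task_glm(task_run, design, mask, slice(0, n_rest_vols))
            activations[cond] = threshold_tmap(act, config.t_threshold)
        except CvrfnError:
            log.error("stage failure: subject=%s condition=%s", sid, cond)
            raise
        log.info(
            "subject=%s condition=%s analysed in %.1f s",
            sid,
            cond,
            time.perf_counter() - t0,
        )

    combined = combined_sig_mask(
        activations["normo"].sig_mask, activations["hyper"].sig_mask
    )
    roi_rows = []
    for cond in CONDITIONS:
        tbl = summarize_roi(
            cvr_results[cond],
            activations[cond],
            label_map,
            voxel_set="combined_sig",
            combined_mask=combined,
        )
        tbl.insert(0, "subject", sid)
        roi_rows.append(tbl)
    roi_table = pd.concat(roi_rows, ignore_index=True)

    counts = pd.DataFrame(
        {
            cond: count_significant(activations[cond].sig_mask, label_map)
            for cond in CONDITIONS
        }
    ).rename_axis("region").reset_index()
    counts.insert(0, "subject", sid)

    _, fn_counts = false_negative_voxels(
        activations["normo"].sig_mask, activations["hyper"].sig_mask, label_map
    )
    low_act = low_activation_high_cvr(
        activations["normo"].dpct,
        cvr_results["normo"].cvr,
        activations["normo"].sig_mask,
        config.dpct_lt,
        config.cvr_gt,
    )
    whole_brain = pd.DataFrame(
        {
            "subject": sid,
            "condition": list(CONDITIONS),
            "mean_cvr": [cvr_results[c].mean_cvr for c in CONDITIONS],
        }
    )
    return SubjectResult(
        subject_id=sid,
        phantom=phantom,
        cvr=cvr_results,
        activation=activations,
        combined_mask=combined,
        roi_table=roi_table,
        counts=counts,
        false_neg_counts=fn_counts,
        low_act_high_cvr_n=int(low_act.sum()),
        whole_brain=whole_brain,
    )


def summarize_group(per_subject_tables) -> pd.DataFrame:
    """Group mean +/- sd (n-1 denominator) per region/condition/modality.

    A region missing for some subject appears with ``missing=True``.
    """
    tables = list(per_subject_tables)
    if len(tables) < 2:
        raise ConfigurationError("group summary needs >= 2 subjects")
    allrows = pd.concat(tables, ignore_index=True)
    grouped = allrows.groupby(["region", "condition", "modality"], sort=False)
    out = grouped.agg(
        mean_dpct=("mean_dpct", "mean"),
        sd_dpct=("mean_dpct", lambda v: v.std(ddof=1)),
        mean_tvalue=("mean_tvalue", "mean"),
        sd_tvalue=("mean_tvalue", lambda v: v.std(ddof=1)),
        mean_n_sig=("n_sig_voxels", "mean"),
        n_subjects=("mean_dpct", "size"),
    ).reset_index()
    n_expected = len(tables)
    out["missing"] = out.n_subjects < n_expected
    return out


def run_cohort(config: CohortConfig) -> CohortReport:
    """Generate and analyse a full cohort; deterministic in master_seed."""
    subjects = [run_subject(config, i) for i in range(config.n_subjects)]

    roi_tables = pd.concat([s.roi_table for s in subjects], ignore_index=True)
    whole_brain = pd.concat([s.whole_brain for s in subjects], ignore_index=True)
    counts = pd.concat([s.counts for s in subjects], ignore_index=True)

    if config.n_subjects >= 2:
        group_table = summarize_group([s.roi_table for s in subjects])
        wb = whole_brain.groupby("condition", sort=False).mean_cvr
        whole_brain_group = pd.DataFrame(
            {
                "condition": list(wb.groups),
                "mean_cvr": wb.mean().values,
                "sd_cvr": wb.std(ddof=1).values,
            }
        )
        pooled = pd.DataFrame(
            {
                "condition": ["pooled"],
                "mean_cvr": [whole_brain.mean_cvr.mean()],
                "sd_cvr": [whole_brain.mean_cvr.std(ddof=1)],
            }
        )
        whole_brain_group = pd.concat([whole_brain_group, pooled], ignore_index=True)
        paired = _paired_tests(roi_tables, counts, config)
        regressions = _regressions(roi_tables)
    else:
        group_table = roi_tables
        whole_brain_group = pd.DataFrame()
        paired = pd.DataFrame()
        regressions = pd.DataFrame()

    fn = pd.DataFrame({s.subject_id: s.false_neg_counts for s in subjects}).T
    fn_summary = pd.DataFrame(
        {
            "region": fn.columns,
            "mean_false_negative_voxels": fn.mean().values,
            "sd_false_negative_voxels": fn.std(ddof=1).values
            if len(fn) > 1
            else np.nan,
        }
    )

    report = CohortReport(
        config=config,
        subjects=subjects,
        roi_tables=roi_tables,
        group_table=group_table,
        whole_brain=whole_brain,
        whole_brain_group=whole_brain_group,
        counts=counts,
        paired_tests=paired,
        regressions=regressions,
        false_negative_summary=fn_summary,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        report.write(out)
        _write_subject_volumes(subjects, out)
        config.to_yaml(out / "cohort_config.yaml")
    return report


def _paired_tests(roi_tables: pd.DataFrame, counts: pd.DataFrame, config) -> pd.DataFrame:
    # Bonferroni factor: 9 regions x measures tested per modality
    measures = [("mean_dpct", "cvr"), ("mean_dpct", "fmri"), ("mean_tvalue", "fmri")]
    factor = len(REGIONS) * len(measures)
    rows = []
    for measure, modality in measures:
        sub = roi_tables[roi_tables.modality == modality]
        wide = sub.pivot_table(
            index="subject", columns=["region", "condition"], values=measure
        )
        for region in REGIONS:
            try:
                res = paired_condition_test(
                    wide[(region, "normo")].to_numpy(),
                    wide[(region, "hyper")].to_numpy(),
                    correction_factor=factor,
                    region=region,
                )
            except ConfigurationError:
                continue
            rows.append(
                {
                    "region": region,
                    "modality": modality,
                    "measure": measure,
                    "t": res.statistic,
                    "raw_p": res.raw_p,
                    "corrected_p": res.corrected_p,
                    "n_subjects": res.n_subjects,
                    "correction_factor": res.correction_factor,
                }
            )
    return pd.DataFrame(rows)


def _regressions(roi_tables: pd.DataFrame) -> pd.DataFrame:
    """ROI-mean CVR vs activation regressions, per condition and pooled,
    for the (dpct, dpct) and (t, t) pairings."""
    rows = []
    for measure in ("mean_dpct", "mean_tvalue"):
        wide = roi_tables.pivot_table(
            index=["subject", "region", "condition"],
            columns="modality",
            values=measure,
        ).dropna()
        for scope in ("normo", "hyper", "pooled"):
            sel = (
                wide
                if scope == "pooled"
                else wide[wide.index.get_level_values("condition") == scope]
            )
            if len(sel) < 3:
                continue
            try:
                res = regress_cvr_vs_dpct(zip(sel["cvr"], sel["fmri"]))
            except DegenerateRegressionError:
                # e.g. noise-free data where every t saturates at the cap
                continue
            rows.append(
                {
                    "measure": measure,
                    "scope": scope,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r": res.r,
                    "p": res.p,
                    "n_points": res.n_points,
                }
            )
    return pd.DataFrame(rows)


def _write_subject_volumes(subjects, out: Path) -> None:
    for s in subjects:
        sdir = out / s.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        nio.save_labels(s.phantom.labels, sdir / "labels.nii")
        for cond in CONDITIONS:
            cv = s.cvr[cond]
            nio.save_volume(cv.cvr, sdir / f"cvr_{cond}.nii")
            nio.save_volume(cv.lag, sdir / f"lag_{cond}.nii")
            nio.save_volume(cv.tvalue, sdir / f"cvr_tvalue_{cond}.nii")
            act = s.activation[cond]
            nio.save_volume(act.tvalue, sdir / f"task_tvalue_{cond}.nii")
            nio.save_volume(act.dpct, sdir / f"task_dpct_{cond}.nii")
            nio.save_volume(
                act.sig_mask.astype(np.uint8), sdir / f"task_sig_{cond}.nii"
            )
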