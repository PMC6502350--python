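"""Generator contracts: stimulus shape, paradigm timing, phantom truth
embedding, and the generative models' exactness in the noise-free limit."""

import numpy as np
import pandas as pd
import pytest

from cvrfn import (
    Co2Trace,
    ProtocolSpec,
    SubjectSpec,
    default_region_truth,
    make_co2_trace,
    make_phantom,
    make_task_paradigm,
    simulate_cvr_run,
    simulate_task_run,
)
from cvrfn.errors import ConfigurationError, ProtocolError
from cvrfn.glm import HrfSpec, hrf_convolved_regressor

from conftest import SMALL_GRID


class TestCo2Trace:
    def test_normo_baseline_and_plateau(self, protocol):
        trace = make_co2_trace(protocol, "normo", 38.0)
        assert trace.petco2.min() == pytest.approx(38.0)
        assert trace.petco2.max() == pytest.approx(48.0)
        # plateau (baseline + step) held for the step duration
        at_plateau = trace.time[np.isclose(trace.petco2, 48.0)]
        assert at_plateau.max() - at_plateau.min() == pytest.approx(
            protocol.step_seconds
        )
        assert trace.duration == pytest.approx(400.0)

    def test_hyper_baseline_is_offset(self, protocol):
        trace = make_co2_trace(protocol, "hyper", 38.0)
        assert trace.petco2[0] == pytest.approx(44.0)
        assert trace.petco2.max() == pytest.approx(54.0)

    def test_zero_step_gives_constant_trace(self):
        proto = ProtocolSpec(step_mmHg=0.0)
        trace = make_co2_trace(proto, "normo", 38.0)
        assert np.allclose(trace.petco2, 38.0)

    def test_clamped_before_and_after_stimulus(self, protocol):
        trace = make_co2_trace(protocol, "normo", 38.0)
        assert np.allclose(trace.petco2[trace.time <= 100.0], 38.0)
        assert np.allclose(trace.petco2[trace.time >= 200.0], 38.0)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ProtocolError):
            ProtocolSpec(tr_seconds=-1.0)
        with pytest.raises(ProtocolError):
            ProtocolSpec(clamp_seconds=350.0, step_seconds=80.0)

    def test_csv_round_trip(self, protocol, tmp_path):
        trace = make_co2_trace(protocol, "normo", 38.0)
        trace.to_csv(tmp_path / "co2.csv")
        back = Co2Trace.from_csv(tmp_path / "co2.csv")
        np.testing.assert_allclose(back.petco2, trace.petco2)


class TestParadigm:
    def test_default_block_timing(self, protocol):
        paradigm, trace = make_task_paradigm(protocol, 38.0)
        assert paradigm.onsets == (30.0, 90.0, 150.0, 210.0)
        assert paradigm.durations == (30.0,) * 4
        assert np.allclose(trace.petco2, 38.0)

    def test_boxcar_volume_count(self, protocol):
        # volumes whose acquisition midpoint falls inside a task block
        paradigm, _ = make_task_paradigm(protocol, 38.0)
        mid = (np.arange(protocol.n_volumes_task) + 0.5) * protocol.tr_seconds
        inside = np.zeros_like(mid, dtype=bool)
        for o, d in zip(paradigm.onsets, paradigm.durations):
            inside |= (mid >= o) & (mid < o + d)
        assert inside.sum() == 60

    def test_zero_blocks(self):
        proto = ProtocolSpec(n_task_blocks=0)
        paradigm, trace = make_task_paradigm(proto, 40.0)
        assert paradigm.n_blocks == 0
        assert np.allclose(trace.petco2, 40.0)

    def test_blocks_exceeding_run_rejected(self):
        with pytest.raises(ProtocolError):
            ProtocolSpec(n_task_blocks=4, task_block_seconds=40.0)


class TestPhantom:
    def test_labels_partition_and_region_truth(self, truth):
        spec = SubjectSpec(seed=5)
        ph = make_phantom(spec)
        sizes = np.bincount(ph.labels.ravel())
        assert len(sizes) == 10 and (sizes[1:] > 50).all()
        for region in truth.index:
            m = ph.region_mask(region)
            assert ph.truth_cvr["normo"][m].mean() == pytest.approx(
                truth.loc[region, "true_cvr_normo"]
            )
            assert np.ptp(ph.truth_cvr["hyper"][m]) == 0  # constant in region
        assert np.all(ph.truth_cvr["normo"][ph.labels == 0] == 0)

    def test_same_seed_identical(self):
        a = make_phantom(SubjectSpec(seed=9), SMALL_GRID)
        b = make_phantom(SubjectSpec(seed=9), SMALL_GRID)
        np.testing.assert_array_equal(a.truth_lag, b.truth_lag)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_lag_quantized_and_in_range(self):
        ph = make_phantom(SubjectSpec(seed=2, lag_range_seconds=(0, 8)))
        lags = ph.truth_lag[ph.labels > 0]
        assert np.all(lags == np.round(lags))
        assert lags.min() >= 0 and lags.max() <= 8

    def test_uniform_truth(self):
        truth = default_region_truth().copy()
        truth.loc[:, :] = 0.2
        ph = make_phantom(SubjectSpec(region_truth=truth, seed=1), SMALL_GRID)
        assert np.all(ph.truth_cvr["normo"][ph.labels > 0] == 0.2)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            make_phantom(SubjectSpec(seed=1), (4, 4, 2))

    def test_bad_region_table_rejected(self):
        truth = default_region_truth().drop(index="sma")
        with pytest.raises(ConfigurationError):
            SubjectSpec(region_truth=truth)
        neg = default_region_truth().copy()
        neg.loc["sma", "true_cvr_normo"] = -0.1
        with pytest.raises(ConfigurationError):
            SubjectSpec(region_truth=neg)


class TestSimulateCvrRun:
    def test_noise_free_regression_recovers_slope(self, protocol):
        truth = default_region_truth().copy()
        truth[["true_cvr_normo", "true_cvr_hyper"]] = 0.3
        spec = SubjectSpec(
            region_truth=truth, noise_sd_pct=0.0, lag_range_seconds=(0, 0), seed=4
        )
        ph = make_phantom(spec, SMALL_GRID)
        trace = make_co2_trace(protocol, "normo", 38.0)
        run = simulate_cvr_run(ph, trace, spec, protocol, "normo")
        mid = run.volume_midpoints()
        co2 = np.interp(mid, trace.time, trace.petco2)
        vox = run.data[ph.labels > 0][0]
        pct = 100 * (vox / vox[:50].mean() - 1)
        slope = np.polyfit(co2, pct, 1)[0]
        assert slope == pytest.approx(0.3, abs=1e-12)

    def test_zero_cvr_gives_flat_baseline(self, protocol):
        truth = default_region_truth().copy()
        truth[["true_cvr_normo", "true_cvr_hyper"]] = 0.0
        spec = SubjectSpec(region_truth=truth, noise_sd_pct=0.0, seed=4)
        ph = make_phantom(spec, SMALL_GRID)
        trace = make_co2_trace(protocol, "normo", 38.0)
        run = simulate_cvr_run(ph, trace, spec, protocol, "normo")
        assert np.allclose(run.data, spec.baseline_signal)

    def test_lag_shows_up_in_cross_correlation(self, protocol):
        # exhaustive integer-shift search oracle on the simulated voxel
        truth = default_region_truth()
        spec = SubjectSpec(
            region_truth=truth, noise_sd_pct=0.0, lag_range_seconds=(4, 4), seed=7
        )
        ph = make_phantom(spec, SMALL_GRID)
        trace = make_co2_trace(protocol, "normo", 38.0)
        run = simulate_cvr_run(ph, trace, spec, protocol, "normo")
        vox = run.data[ph.labels > 0][0]
        mid = run.volume_midpoints()
        best, best_r = None, -np.inf
        for shift in range(0, 11):
            co2 = np.interp(mid - shift, trace.time, trace.petco2)
            r = np.corrcoef(vox, co2)[0, 1]
            if r > best_r:
                best, best_r = shift, r
        assert best == 4

    def test_doubling_s0_leaves_percent_signal_unchanged(self, protocol):
        trace = make_co2_trace(protocol, "normo", 38.0)
        pcts = []
        for s0 in (800.0, 1600.0):
            spec = SubjectSpec(noise_sd_pct=1.0, seed=13, baseline_signal=s0)
            ph = make_phantom(spec, SMALL_GRID)
            run = simulate_cvr_run(ph, trace, spec, protocol, "normo")
            vox = run.data[ph.labels > 0]
            pcts.append(100 * (vox / vox[:, :50].mean(axis=1, keepdims=True) - 1))
        np.testing.assert_allclose(pcts[0], pcts[1], rtol=1e-10)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            SubjectSpec(noise_sd_pct=-1.0)

    def test_seeded_determinism(self, protocol):
        spec = SubjectSpec(noise_sd_pct=1.0, seed=21)
        trace = make_co2_trace(protocol, "normo", 38.0)
        runs = [
            simulate_cvr_run(make_phantom(spec, SMALL_GRID), trace, spec, protocol)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].data, runs[1].data)


class TestSimulateTaskRun:
    def test_noise_free_glm_recovers_dpct(self, protocol):
        truth = default_region_truth().copy()
        truth[["true_dpct_normo", "true_dpct_hyper"]] = 0.85
        spec = SubjectSpec(region_truth=truth, noise_sd_pct=0.0, seed=4)
        ph = make_phantom(spec, SMALL_GRID)
        paradigm, _ = make_task_paradigm(protocol, 38.0)
        run = simulate_task_run(ph, paradigm, spec, protocol, "normo")
        reg = hrf_convolved_regressor(
            paradigm, HrfSpec(), protocol.n_volumes_task, protocol.tr_seconds
        )
        vox = run.data[ph.labels > 0][0]
        pct = 100 * (vox / vox[:15].mean() - 1)
        slope = np.polyfit(reg, pct, 1)[0]
        assert slope == pytest.approx(0.85, abs=1e-10)

    def test_zero_dpct_stays_subthreshold(self, protocol):
        truth = default_region_truth().copy()
        truth[["true_dpct_normo", "true_dpct_hyper"]] = 0.0
        spec = SubjectSpec(region_truth=truth, noise_sd_pct=1.0, seed=8)
        ph = make_phantom(spec, SMALL_GRID)
        paradigm, _ = make_task_paradigm(protocol, 38.0)
        run = simulate_task_run(ph, paradigm, spec, protocol, "normo")
        from cvrfn import build_design, fit_task_glm, make_analysis_mask, threshold_tmap

        reg = hrf_convolved_regressor(
            paradigm, HrfSpec(), protocol.n_volumes_task, protocol.tr_seconds
        )
        mask = make_analysis_mask(ph.gm_prob, ph.wm_prob)
        act = fit_task_glm(run, build_design(reg, drift_order=2), mask, slice(0, 15))
        assert abs(act.dpct[mask].mean()) < 0.1
        assert threshold_tmap(act, 3.43).sig_mask.sum() <= 2

    def test_noisy_estimate_within_3_se_of_truth(self, protocol):
        spec = SubjectSpec(noise_sd_pct=1.0, seed=17)
        ph = make_phantom(spec, SMALL_GRID)
        paradigm, _ = make_task_paradigm(protocol, 38.0)
        run = simulate_task_run(ph, paradigm, spec, protocol, "normo")
        reg = hrf_convolved_regressor(
            paradigm, HrfSpec(), protocol.n_volumes_task, protocol.tr_seconds
        )
        m = ph.region_mask("precentral_right")
        vox = run.data[m][0]
        pct = 100 * (vox / vox[:15].mean() - 1)
        X = np.column_stack([reg, np.ones_like(reg)])
        beta, rss = np.linalg.lstsq(X, pct, rcond=None)[:2]
        se = np.sqrt(
            rss[0] / (len(pct) - 2) * np.linalg.inv(X.T @ X)[0, 0]
        )
        assert abs(beta[0] - 0.85) < 3 * se
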