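"""z-score outlier statistic, dual-threshold calling, and recurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cytodet import (
    SampleMetadata,
    aggregate_recurrence,
    call_outliers,
    default_paper_scenario,
    simulate_expression,
    summarize_outlier_burden,
    zscore_outlier,
)
from cytodet.outliers import calls_from_records


class TestZscoreOutlier:
    def test_center_of_null(self):
        controls = [7.0, 8.0, 9.0, 8.5]
        call = zscore_outlier(np.mean(controls), controls)
        assert call.z == 0.0
        assert call.p == 1.0
        assert not call.passes

    def test_textbook_example(self):
        # oracle: numerical integration of the standard normal density
        call = zscore_outlier(6.0, [1, 2, 3, 4, 5])
        assert call.delta == pytest.approx(3.0)
        assert call.z == pytest.approx(3.0 / np.sqrt(2.5), abs=1e-12)
        tail, _ = __import__("scipy.integrate", fromlist=["quad"]).quad(
            lambda u: np.exp(-u * u / 2) / np.sqrt(2 * np.pi), call.z, np.inf
        )
        assert call.p == pytest.approx(2 * tail, abs=1e-9)
        assert call.p == pytest.approx(0.0578, abs=2e-4)
        assert not call.passes

    def test_strong_under_expression_passes(self):
        # control mean 8.0, sample SD 0.2 by construction
        controls = 8.0 + 0.2 * np.array([-1, 1, -1, 1, -1, 1]) * np.sqrt(5 / 6)
        assert np.std(controls, ddof=1) == pytest.approx(0.2)
        call = zscore_outlier(6.5, controls)
        assert call.delta == pytest.approx(-1.5)
        assert call.z == pytest.approx(-7.5)
        assert call.p < 1e-13
        assert call.passes and call.direction == "under"

    def test_fold_change_threshold_binds(self):
        # enormous |z| but |delta| below 1 log2 unit fails the FC criterion
        controls = 8.0 + 0.01 * np.array([-1, 1, -1, 1]) * np.sqrt(3 / 4)
        call = zscore_outlier(8.9, controls)
        assert call.p < 1e-10
        assert abs(call.delta) < 1.0
        assert not call.passes

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            zscore_outlier(1.0, [1.0, 2.0])
        with pytest.raises(ValueError, match="SD is zero"):
            zscore_outlier(1.0, [2.0, 2.0, 2.0])

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        test=st.floats(-5, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_affine_invariance(self, shift, scale, test):
        controls = np.array([7.2, 8.1, 8.9, 7.7, 8.4])
        base = zscore_outlier(test + 8.0, controls)
        shifted = zscore_outlier(test + 8.0 + shift, controls + shift)
        assert shifted.z == pytest.approx(base.z, rel=1e-9, abs=1e-9)
        assert shifted.p == pytest.approx(base.p, rel=1e-6, abs=1e-12)
        assert shifted.passes == base.passes
        scaled = zscore_outlier(scale * (test + 8.0), scale * controls)
        assert scaled.z == pytest.approx(base.z, rel=1e-9, abs=1e-9)
        assert scaled.delta == pytest.approx(scale * base.delta, rel=1e-9, abs=1e-9)


def null_cohort(n_probes, n_control=42, n_case=58, sd=0.5, seed=0):
    from cytodet import SimScenario
    sc = SimScenario(
        n_control=n_control, n_case=n_case, n_probes=n_probes,
        probe_sd_range=(sd, sd), eqtl=None, seed=seed,
    )
    return simulate_expression(sc)


class TestCallOutliers:
    def test_case_samples_never_enter_reference(self):
        # a grossly aberrant case cannot mask itself: reference stats are
        # computed from controls only
        cohort = null_cohort(5, n_control=10, n_case=3, seed=1)
        vals = cohort.expression.values.copy()
        vals.loc["PROBE_000000", "CD001"] += 50.0
        from cytodet import ExpressionMatrix
        calls = call_outliers(ExpressionMatrix(vals), cohort.metadata)
        hit = calls[(calls["probe_id"] == "PROBE_000000") & (calls["sample_id"] == "CD001")]
        assert hit["passes"].item()
        # other cases on that probe unaffected by the aberrant case
        others = calls[(calls["probe_id"] == "PROBE_000000") & (calls["sample_id"] != "CD001")]
        assert not others["passes"].any()

    def test_planted_carriers_flagged_under(self, small_planted_cohort):
        cohort = small_planted_cohort
        calls = call_outliers(cohort.expression, cohort.metadata)
        pid = "PROBE_000000"
        flagged = calls[(calls["probe_id"] == pid) & calls["passes"]]
        truth = set(cohort.truth.carriers[pid])
        hits = set(flagged.loc[flagged["direction"] == "under", "sample_id"])
        # per-carrier sensitivity ~0.98 at effect -1.5, SD 0.25: expect at
        # least 5 of the 7 carriers, and no spurious carriers at 4 true SDs
        assert len(hits & truth) >= 5
        assert hits <= truth

    def test_matches_scalar_statistic(self):
        cohort = null_cohort(4, n_control=8, n_case=2, seed=2)
        calls = call_outliers(cohort.expression, cohort.metadata)
        controls = cohort.metadata.control_samples
        for _, row in calls.iterrows():
            ref = cohort.expression.values.loc[row["probe_id"], controls]
            single = zscore_outlier(
                cohort.expression.values.loc[row["probe_id"], row["sample_id"]], ref
            )
            assert row["z"] == pytest.approx(single.z, abs=1e-12)
            assert row["p"] == pytest.approx(single.p, abs=1e-12)

    def test_no_cases_rejected(self):
        cohort = null_cohort(3, n_control=6, n_case=2, seed=3)
        meta = SampleMetadata(cohort.metadata.table.assign(cohort="control"))
        with pytest.raises(ValueError, match="no case samples"):
            call_outliers(cohort.expression, meta)

    def test_stimulated_samples_warn(self, caplog):
        cohort = null_cohort(3, n_control=6, n_case=2, seed=4)
        meta = SampleMetadata(cohort.metadata.table.assign(stimulation="stimulated"))
        with caplog.at_level("WARNING"):
            call_outliers(cohort.expression, meta)
        assert any("unstimulated" in r.message for r in caplog.records)


class TestNullCalibration:
    def test_pass_rate_matches_monte_carlo_oracle(self):
        """At control n=42 and probe SD 0.5 the P criterion binds; the
        empirical pass rate exceeds the nominal 0.005 because of plug-in
        mean/SD estimation and must match a brute-force oracle."""
        n_probes = 3500  # 3500 x 58 = 203k tests
        cohort = null_cohort(n_probes, sd=0.5, seed=10)
        calls = call_outliers(cohort.expression, cohort.metadata)
        rate = calls["passes"].mean()

        # independent oracle: fresh normal draws, plug-in statistics
        rng = np.random.default_rng(99)
        n_oracle = 400_000
        ctrl = rng.normal(0, 0.5, (n_oracle // 58 + 1, 42))
        m, s = ctrl.mean(1), ctrl.std(1, ddof=1)
        tests = rng.normal(0, 0.5, (ctrl.shape[0], 58))
        delta = tests - m[:, None]
        z = delta / s[:, None]
        hit = (2 * stats.norm.sf(np.abs(z)) < 0.005) & (np.abs(delta) > 1.0)
        oracle = hit.mean()
        n_tests = calls.shape[0]
        se = np.sqrt(oracle * (1 - oracle) * (1 / n_tests + 1 / hit.size))
        assert abs(rate - oracle) < 3 * se
        assert oracle > 0.005  # plug-in inflation is real

    def test_fold_change_binds_at_low_sd(self):
        """At probe SD 0.2 the |delta| > 1 criterion (5 true SDs)
        dominates and the pass rate collapses toward P(|Z| > 5)."""
        cohort = null_cohort(4000, sd=0.2, seed=11)
        calls = call_outliers(cohort.expression, cohort.metadata)
        assert calls["passes"].mean() < 5e-5


class TestRecovery:
    def test_planted_carrier_sensitivity(self):
        """Carriers at |effect| 1.5 and SD 0.25 are recovered with
        sensitivity >= 0.95 (per carrier, across seeded replicates)."""
        recovered = total = 0
        for seed in range(40):
            sc = default_paper_scenario(seed=seed)
            sc.n_probes = 60
            sc.__post_init__()
            cohort = simulate_expression(sc)
            calls = call_outliers(cohort.expression, cohort.metadata)
            pid = "PROBE_000000"
            hits = set(
                calls.loc[
                    (calls["probe_id"] == pid) & calls["passes"]
                    & (calls["direction"] == "under"),
                    "sample_id",
                ]
            )
            truth = set(cohort.truth.carriers[pid])
            recovered += len(hits & truth)
            total += len(truth)
        assert recovered / total >= 0.95


class TestRecurrence:
    def test_empty_calls(self):
        table = aggregate_recurrence(calls_from_records([]))
        assert table.empty

    def make_calls(self, rows):
        """rows: list of (probe, sample, direction, passes)."""
        recs = []
        for probe, sample, direction, passes in rows:
            delta = -2.0 if direction == "under" else 2.0
            recs.append(
                dict(probe_id=probe, sample_id=sample, z=delta / 0.2, p=1e-6,
                     delta=delta, direction=direction, passes=passes)
            )
        return pd.DataFrame(recs)

    def test_three_under_carriers_included(self):
        calls = self.make_calls(
            [("P1", f"CD{i}", "under", True) for i in range(3)]
            + [("P1", "CD9", "under", False)]
        )
        table = aggregate_recurrence(calls, min_carriers=3)
        assert table.loc["P1", "count_under"] == 3
        assert table.loc["P1", "count_over"] == 0
        assert not table.loc["P1", "both_directions"]

    def test_mixed_directions_and_threshold(self):
        calls = self.make_calls(
            [("P1", "CD1", "under", True), ("P1", "CD2", "under", True),
             ("P1", "CD3", "over", True)]
        )
        assert aggregate_recurrence(calls, min_carriers=3).empty
        table = aggregate_recurrence(calls, min_carriers=1)
        assert table.loc["P1", "count_under"] == 2
        assert table.loc["P1", "count_over"] == 1
        assert bool(table.loc["P1", "both_directions"])

    def test_call_conservation(self, small_planted_cohort):
        cohort = small_planted_cohort
        calls = call_outliers(cohort.expression, cohort.metadata)
        table = aggregate_recurrence(calls, min_carriers=1)
        assert (table["count_under"] + table["count_over"]).sum() == calls["passes"].sum()


class TestBurdenSummary:
    def test_study_scale_arithmetic(self):
        # 385 flagged probes of 10468 expressed -> 3.7% to one decimal
        from cytodet import ExpressionMatrix
        n_probes = 10_468
        probes = [f"P{i}" for i in range(n_probes)]
        expr = ExpressionMatrix(
            pd.DataFrame(np.zeros((n_probes, 1)), index=probes, columns=["CD1"])
        )
        rows = [(f"P{i}", "CD1", "under", True) for i in range(385)]
        calls = TestRecurrence().make_calls(rows)
        out = summarize_outlier_burden(calls, expr)
        assert out["n_probes_flagged_any"] == 385
        assert out["percent_flagged"] == 3.7

    def test_zero_and_full(self, small_matrix):
        empty = TestRecurrence().make_calls([("P0", "CD1", "under", False)])
        assert summarize_outlier_burden(empty, small_matrix)["percent_flagged"] == 0.0
        full = TestRecurrence().make_calls(
            [(p, "CD1", "over", True) for p in small_matrix.probe_ids]
        )
        assert summarize_outlier_burden(full, small_matrix)["percent_flagged"] == 100.0

    def test_both_direction_counts_independent(self, small_matrix):
        calls = TestRecurrence().make_calls(
            [("P0", "CD1", "under", True), ("P0", "CD2", "over", True),
             ("P1", "CD1", "over", True)]
        )
        out = summarize_outlier_burden(calls, small_matrix)
        assert out["n_under"] == 1
        assert out["n_over"] == 2
        assert out["n_both"] == 1
        assert out["n_probes_flagged_any"] == 2
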