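"""Stage correlations, adjusted subtype comparisons, sliding windows,
LOESS trajectories, and the simplified USSLB stager."""

import numpy as np
import pandas as pd
import pytest

import ordsustain as osn
from ordsustain.characterize import CorrelationResult


class TestStageCorrelation:
    def test_monotone_covariate_gives_rho_one(self, synthetic_assignments):
        frame, _ = synthetic_assignments
        cov = pd.Series(
            frame["stage"].to_numpy() * 2.0 + 1,
            index=frame["subject_id"],
        )
        (res,) = osn.stage_correlation(frame, cov)
        assert res.rho == pytest.approx(1.0)
        assert res.pvalue < 1e-10

    def test_independent_covariate_rho_small(self, synthetic_assignments):
        frame, _ = synthetic_assignments
        rng = np.random.default_rng(0)
        cov = pd.Series(rng.normal(size=len(frame)), index=frame["subject_id"])
        (res,) = osn.stage_correlation(frame, cov)
        assert abs(res.rho) < 0.15

    def test_constant_covariate_flagged_degenerate(self, synthetic_assignments):
        frame, _ = synthetic_assignments
        cov = pd.Series(5.0, index=frame["subject_id"])
        (res,) = osn.stage_correlation(frame, cov)
        assert res.degenerate and np.isnan(res.rho)

    def test_by_subtype_returns_group_results(self, synthetic_assignments):
        frame, _ = synthetic_assignments
        cov = pd.Series(
            frame["stage"].to_numpy() + 0.0, index=frame["subject_id"]
        )
        results = osn.stage_correlation(frame, cov, by_subtype=True)
        assert {r.group for r in results} == {1, 2}
        assert all(isinstance(r, CorrelationResult) for r in results)

    def test_too_few_observations_rejected(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "subtype": [1, 1],
                "stage": [1, 2],
                "max_posterior": [0.9, 0.9],
                "included": [True, True],
                "reason": ["", ""],
            }
        )
        cov = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            osn.stage_correlation(frame, cov)


class TestSubtypeComparison:
    def test_identical_outcomes_give_zero_estimates(self, synthetic_assignments):
        frame, covs = synthetic_assignments
        outcome = pd.Series(3.0, index=frame["subject_id"])
        table = osn.subtype_comparison(outcome, "continuous", frame, covs)
        assert np.allclose(table["estimate"], 0.0, atol=1e-10)

    def test_known_continuous_effect_recovered(self, synthetic_assignments):
        frame, covs = synthetic_assignments
        rng = np.random.default_rng(1)
        effect = np.where(frame["subtype"] == 2, 2.0, 0.0)
        outcome = pd.Series(
            effect + rng.normal(0, 1, len(frame)), index=frame["subject_id"]
        )
        table = osn.subtype_comparison(outcome, "continuous", frame, covs)
        row = table.iloc[0]
        assert row["estimate"] == pytest.approx(2.0, abs=3 * row["se"])
        assert row["pvalue"] < 1e-6

    def test_binary_log_odds_recovered_at_n600(self):
        rng = np.random.default_rng(2)
        n = 600
        subtype = rng.integers(1, 3, n)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "subtype": subtype,
                "stage": rng.integers(1, 41, n),
                "max_posterior": 0.9,
                "included": True,
                "reason": "",
            }
        )
        covs = pd.DataFrame(
            {
                "subject_id": frame["subject_id"],
                "age_at_death": rng.normal(82, 7, n),
                "sex": rng.choice(["F", "M"], n),
            }
        ).set_index("subject_id")
        logit = -0.5 + 1.0 * (subtype == 2)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        outcome = pd.Series(y, index=frame["subject_id"])
        table = osn.subtype_comparison(outcome, "binary", frame, covs)
        row = table.iloc[0]
        assert row["estimate"] == pytest.approx(1.0, abs=2 * row["se"])

    def test_nominal_outcome_one_vs_reference(self, synthetic_assignments):
        frame, covs = synthetic_assignments
        rng = np.random.default_rng(3)
        outcome = pd.Series(
            rng.choice(["x", "y", "z"], len(frame), p=[0.5, 0.3, 0.2]),
            index=frame["subject_id"],
        )
        table = osn.subtype_comparison(outcome, "nominal", frame, covs)
        # one row per pair per non-reference category
        assert set(table["outcome_category"]) == {"y", "z"}

    def test_fdr_adjusted_pvalues_monotone_and_larger(self, synthetic_assignments):
        frame, covs = synthetic_assignments
        rng = np.random.default_rng(4)
        outcome = pd.Series(
            rng.normal(size=len(frame)), index=frame["subject_id"]
        )
        table = osn.subtype_comparison(
            outcome, "continuous", frame, covs, fdr=True
        )
        assert (table["p_fdr"] >= table["pvalue"] - 1e-12).all()

    def test_unknown_kind_rejected(self, synthetic_assignments):
        frame, covs = synthetic_assignments
        outcome = pd.Series(1.0, index=frame["subject_id"])
        with pytest.raises(ValueError):
            osn.subtype_comparison(outcome, "ordinal-ish", frame, covs)

    def test_null_simulation_type_I_error_near_nominal(self):
        # rejection rate of the pairwise test under a true null, at alpha=.05
        rng = np.random.default_rng(5)
        n, reps = 150, 400
        subtype = rng.integers(1, 3, n)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "subtype": subtype,
                "stage": rng.integers(1, 41, n),
                "max_posterior": 0.9,
                "included": True,
                "reason": "",
            }
        )
        covs = pd.DataFrame(
            {
                "subject_id": frame["subject_id"],
                "age_at_death": rng.normal(82, 7, n),
                "sex": rng.choice(["F", "M"], n),
            }
        ).set_index("subject_id")
        rejections = 0
        for _ in range(reps):
            outcome = pd.Series(rng.normal(size=n), index=frame["subject_id"])
            table = osn.subtype_comparison(outcome, "continuous", frame, covs)
            rejections += int(table.iloc[0]["pvalue"] < 0.05)
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9


class TestFDR:
    def test_bh_monotone_in_raw_order(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        adj = osn.fdr_correct(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestSlidingWindow:
    def _inputs(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "subtype": rng.integers(1, 3, n),
                "stage": rng.integers(1, 41, n),
                "max_posterior": 0.9,
                "included": True,
                "reason": "",
            }
        )
        covs = pd.DataFrame(
            {
                "subject_id": frame["subject_id"],
                "age_at_death": rng.normal(82, 7, n),
                "sex": rng.choice(["F", "M"], n),
            }
        ).set_index("subject_id")
        outcome = pd.Series(rng.normal(size=n), index=frame["subject_id"])
        return outcome, frame, covs

    def test_default_width_yields_31_windows(self):
        outcome, frame, covs = self._inputs()
        table = osn.sliding_window_analysis(outcome, "continuous", frame, covs)
        windows = table[["window_start", "window_end"]].drop_duplicates()
        assert len(windows) == 31
        assert windows.iloc[0].tolist() == [1, 10]
        assert windows.iloc[-1].tolist() == [31, 40]

    def test_full_width_single_window(self):
        outcome, frame, covs = self._inputs()
        table = osn.sliding_window_analysis(
            outcome, "continuous", frame, covs, width=40
        )
        assert table[["window_start", "window_end"]].drop_duplicates().shape[0] == 1

    def test_window_count_formula(self):
        outcome, frame, covs = self._inputs(n=800, seed=1)
        for width in (5, 10, 20, 39):
            table = osn.sliding_window_analysis(
                outcome, "continuous", frame, covs, width=width
            )
            n_windows = table[["window_start", "window_end"]].drop_duplicates().shape[0]
            assert n_windows == 40 - width + 1

    def test_empty_window_flagged_not_dropped(self):
        outcome, frame, covs = self._inputs(n=60, seed=2)
        # concentrate everyone in stages 1..5 so late windows are empty
        frame = frame.assign(stage=np.clip(frame["stage"], 1, 5))
        table = osn.sliding_window_analysis(outcome, "continuous", frame, covs)
        assert (table["status"] == "insufficient-n").any()
        windows = table[["window_start", "window_end"]].drop_duplicates()
        assert len(windows) == 31

    def test_narrow_width_rejected(self):
        outcome, frame, covs = self._inputs()
        with pytest.raises(ValueError):
            osn.sliding_window_analysis(outcome, "continuous", frame, covs, width=1)


class TestPeripheralTrajectory:
    def _frame(self, stages, subtype=1):
        n = len(stages)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "subtype": subtype,
                "stage": stages,
                "max_posterior": 0.9,
                "included": True,
                "reason": "",
            }
        )

    def test_constant_input_reproduced(self):
        rng = np.random.default_rng(0)
        stages = rng.integers(1, 41, 80)
        frame = self._frame(stages)
        totals = pd.Series(7.0, index=frame["subject_id"])
        fit = osn.peripheral_trajectory(frame, totals)
        assert np.allclose(fit["fitted"], 7.0, atol=1e-8)

    def test_changepoint_pattern_recovered(self):
        # zero before stage 12, linear rise after: the smoothed curve stays
        # near zero early and increases past the onset
        rng = np.random.default_rng(1)
        stages = rng.integers(1, 41, 400)
        true_mean = np.clip((stages - 12) * 1.2, 0, 28)
        totals = np.clip(true_mean + rng.normal(0, 1.5, 400), 0, 28)
        frame = self._frame(stages)
        fit = osn.peripheral_trajectory(
            frame, pd.Series(totals, index=frame["subject_id"]), span=0.4
        )
        early = fit[fit["stage"] < 8]["fitted"]
        late = fit[fit["stage"] >= 20]["fitted"].to_numpy()
        assert (early < 2.0).all()
        assert (np.diff(late) > -0.3).all() and late[-1] > late[0]

    def test_values_clipped_to_score_range(self):
        rng = np.random.default_rng(2)
        stages = rng.integers(1, 41, 60)
        frame = self._frame(stages)
        totals = pd.Series(
            rng.uniform(0, 28, 60), index=frame["subject_id"]
        )
        fit = osn.peripheral_trajectory(frame, totals)
        assert fit["fitted"].between(0, 28).all()

    def test_small_subtype_skipped_with_warning(self):
        frame = self._frame([1, 2, 3, 4, 5])
        totals = pd.Series(1.0, index=frame["subject_id"])
        with pytest.warns(UserWarning, match="skipped"):
            fit = osn.peripheral_trajectory(frame, totals)
        assert fit.empty


class TestUSSLB:
    def _scores(self, **overrides):
        base = {r: 0 for r in osn.STANDARD_REGIONS}
        base.update(overrides)
        return base

    def test_olfactory_only_is_stage_I(self):
        assert osn.usslb_stage(self._scores(olfactory_bulb=1)) == "I"

    def test_all_zero_unclassifiable(self):
        assert osn.usslb_stage(self._scores()) == "unclassifiable"

    def test_neocortical_moderate_is_stage_IV(self):
        scores = self._scores(
            olfactory_bulb=3, medulla=2, amygdala=3, temporal=3
        )
        assert osn.usslb_stage(scores) == "IV"

    def test_brainstem_predominant_IIa(self):
        scores = self._scores(olfactory_bulb=2, medulla=2, pons=2)
        assert osn.usslb_stage(scores) == "IIa"

    def test_limbic_predominant_IIb(self):
        scores = self._scores(olfactory_bulb=2, amygdala=2, transentorhinal=1)
        assert osn.usslb_stage(scores) == "IIb"

    def test_comparable_brainstem_and_limbic_III(self):
        scores = self._scores(
            olfactory_bulb=2, medulla=2, pons=1, amygdala=2, transentorhinal=1
        )
        assert osn.usslb_stage(scores) == "III"

    def test_wrong_region_set_rejected(self):
        with pytest.raises(ValueError):
            osn.usslb_stage({"not_a_region": 1})

    def test_cross_tabulates_against_model_subtypes(self):
        # brainstem-first simulated subjects should rarely be IIb
        seqs, fractions = osn.preset_three_subtypes()
        table, truth = osn.simulate_cohort(
            seqs, fractions, n_subjects=300, noise_sd=0.0, seed=9
        )
        labels = [
            osn.usslb_stage(table.data.iloc[j]) for j in range(table.n_subjects)
        ]
        labels = np.array(labels)
        s3 = truth.subtype == 2
        mid = (truth.stage >= 3) & (truth.stage <= 20)
        sel = s3 & mid
        assert sel.any()
        assert (labels[sel] == "IIb").mean() < 0.05
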