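import numpy as np
import pandas as pd
import pytest

from zoomfit.design import ParameterSpace
from zoomfit.lookup import (
    Clause,
    SuccessCriteria,
    assemble_guideline_set,
    evaluate_success,
    evaluate_success_batch,
    score_distance,
)


def toy_metrics(n=30, p=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"m{j}" for j in range(p)])


class TestScoreDistance:
    def test_identical_simulation_has_zero_distance(self):
        M = toy_metrics()
        target = M.iloc[3].copy()
        rep = score_distance(M, target)
        assert rep.rmsd.iloc[3] == pytest.approx(0.0, abs=1e-10)
        assert rep.ranking[0] == 3

    def test_symmetric_pair_has_equal_distances(self):
        target = pd.Series({"a": 0.0, "b": 0.0})
        M = pd.DataFrame(
            {"a": [1.0, -1.0, 0.3, 2.0, -0.7], "b": [2.0, -2.0, 0.1, 0.5, 0.9]}
        )
        rep = score_distance(M, target)
        assert rep.rmsd.iloc[0] == pytest.approx(rep.rmsd.iloc[1], rel=1e-10)

    def test_full_rank_oracle(self):
        # independent route: standardize the stacked matrix, full
        # eigendecomposition, RMSD over all components
        M = toy_metrics(n=5, p=3, seed=4)
        target = pd.Series([0.1, -0.2, 0.3], index=M.columns)
        rep = score_distance(M, target)
        stack = np.vstack([M.to_numpy(), target.to_numpy()[None, :]])
        Z = (stack - stack.mean(0)) / stack.std(0, ddof=1)
        w, V = np.linalg.eigh(np.cov(Z.T, ddof=1))
        S = Z @ V  # all components, any order/sign: distances are invariant
        d = np.sqrt(((S[:-1] - S[-1]) ** 2).mean(axis=1))
        assert rep.k99 <= 3
        if rep.k99 == 3:  # only comparable when no component was truncated
            assert np.allclose(rep.rmsd.to_numpy(), d, atol=1e-8)
        # ranking agrees regardless of k99 on well-separated data
        assert list(rep.ranking) == list(np.argsort(d, kind="stable"))

    def test_invariant_under_column_reordering(self):
        M = toy_metrics(seed=7)
        target = pd.Series(np.zeros(5), index=M.columns)
        r1 = score_distance(M, target)
        cols = list(M.columns[::-1])
        r2 = score_distance(M[cols], target[cols])
        assert np.allclose(r1.rmsd.to_numpy(), r2.rmsd.to_numpy(), atol=1e-10)

    def test_duplicate_of_target_ranks_first(self):
        M = toy_metrics(seed=9)
        target = pd.Series(np.linspace(-1, 1, 5), index=M.columns)
        M2 = pd.concat([M, target.to_frame().T], ignore_index=True)
        rep = score_distance(M2, target)
        assert rep.ranking[0] == len(M2) - 1
        assert rep.rmsd.iloc[-1] == pytest.approx(0.0, abs=1e-10)


class TestGuidelineSet:
    def make_report(self, n):
        M = toy_metrics(n=n, p=4, seed=1)
        target = pd.Series(np.zeros(4), index=M.columns)
        return score_distance(M, target), pd.DataFrame(
            np.random.default_rng(2).uniform(size=(n, 2)), columns=["p1", "p2"]
        )

    def test_twenty_plus_prediction_is_21(self):
        rep, params = self.make_report(500)
        pred = pd.Series({"p1": 0.5, "p2": np.nan})  # p2 failed the screen
        gs = assemble_guideline_set(rep, params, prediction=pred, k=20)
        assert len(gs) == 21
        assert gs.sources[-1] == "metamodel"
        # unscreened entry filled with the mean of the 20 nearest rows
        nearest = params.loc[list(rep.ranking[:20])]
        assert gs.params.iloc[-1]["p2"] == pytest.approx(nearest["p2"].mean())

    def test_short_batch_uses_all_with_warning(self):
        rep, params = self.make_report(12)
        with pytest.warns(UserWarning, match="short"):
            gs = assemble_guideline_set(rep, params, k=20)
        assert len(gs) == 12

    def test_no_prediction_row_without_prediction(self):
        rep, params = self.make_report(50)
        gs = assemble_guideline_set(rep, params, prediction=None, k=20)
        assert len(gs) == 20
        assert all(s == "simulation" for s in gs.sources)

    def test_prediction_clamped_to_hard_constraints(self):
        rep, params = self.make_report(50)
        space = ParameterSpace(
            ("p1", "p2"), np.array([0.0, 0.0]), np.array([1.0, 1.0]),
            np.array([0.0, 0.0]), np.array([1.0, 0.8]),
        )
        pred = pd.Series({"p1": 5.0, "p2": 0.9})
        gs = assemble_guideline_set(rep, params, prediction=pred, k=20, space=space)
        assert gs.params.iloc[-1]["p1"] == 1.0
        assert gs.params.iloc[-1]["p2"] == 0.8


class TestSuccessCriteria:
    def criteria(self):
        return SuccessCriteria(
            (
                Clause("RT50", 1.0, 16.0, 30.0),
                Clause("Peak", 1.1, 73.0, 90.0),
                Clause("RMSDforce", 1.0, None, 0.15, upper_strict=True),
            )
        )

    def test_boundary_cases(self):
        crit = self.criteria()
        base = pd.Series({"RT50@1": 16.0, "Peak@1.1": 80.0, "RMSDforce@1": 0.10})
        ok, rep = evaluate_success(base, crit)
        assert ok and rep["passed"].all()

        bad_peak = base.copy()
        bad_peak["Peak@1.1"] = 95.0
        ok, rep = evaluate_success(bad_peak, crit)
        assert not ok
        assert not rep.loc["Peak@1.1", "passed"]

        at_cap = base.copy()
        at_cap["RMSDforce@1"] = 0.15  # strict "less than": exactly 0.15 fails
        ok, _ = evaluate_success(at_cap, crit)
        assert not ok

    def test_missing_metric_fails_with_flag(self):
        crit = self.criteria()
        v = pd.Series({"RT50@1": 20.0, "Peak@1.1": 80.0})
        ok, rep = evaluate_success(v, crit)
        assert not ok
        assert rep.loc["RMSDforce@1", "missing"]

    def test_monotone_under_interval_relaxation(self):
        rng = np.random.default_rng(3)
        v = pd.Series({"RT50@1": rng.uniform(10, 35), "Peak@1.1": rng.uniform(60, 100),
                       "RMSDforce@1": rng.uniform(0, 0.3)})
        tight = self.criteria()
        loose = SuccessCriteria(
            tuple(
                Clause(c.metric, c.lam,
                       None if c.lower is None else c.lower - 5,
                       None if c.upper is None else c.upper + 5,
                       upper_strict=c.upper_strict)
                for c in tight.clauses
            )
        )
        ok_tight, _ = evaluate_success(v, tight)
        ok_loose, _ = evaluate_success(v, loose)
        assert ok_loose or not ok_tight  # relaxing never breaks a pass

    def test_batch_evaluation_matches_scalar(self):
        crit = self.criteria()
        df = pd.DataFrame(
            {
                "RT50@1": [16.0, 15.9, 20.0],
                "Peak@1.1": [80.0, 80.0, 95.0],
                "RMSDforce@1": [0.1, 0.1, 0.1],
            }
        )
        batch = evaluate_success_batch(df, crit)
        scalar = [evaluate_success(df.iloc[i], crit)[0] for i in range(3)]
        assert list(batch) == scalar == [True, False, False]

    def test_config_round_trip(self, tmp_path):
        crit = self.criteria()
        path = tmp_path / "criteria.yaml"
        crit.to_config(path)
        crit2 = SuccessCriteria.from_config(path)
        assert crit2 == crit
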