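"""The ensemble selection engine: screens, backward elimination,
recurrence ranking, and AIC-nadir panel sizing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import uromet.selection as selmod
from uromet import (
    CandidateModel,
    SelectionConfig,
    aic_backward_eliminate,
    fit_logistic,
    multivariable_prune,
    rank_by_recurrence,
    run_selection_ensemble,
    select_panel_size_aic_nadir,
    univariate_screen,
)


def _df(X):
    return pd.DataFrame(X, columns=[f"F{j}" for j in range(X.shape[1])])


class TestUnivariateScreen:
    def test_perfectly_separating_feature_is_kept(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = _df(y[:, None].astype(float))
        assert univariate_screen(X, y, 0.1) == ["F0"]

    def test_alpha_one_keeps_all_nonconstant(self, rng):
        X = _df(rng.normal(size=(40, 4)))
        X["F2"] = 1.0  # constant: slope undefined, excluded
        y = (rng.random(40) < 0.5).astype(int)
        assert univariate_screen(X, y, 1.0) == ["F0", "F1", "F3"]

    def test_noise_kept_at_rate_alpha(self):
        """A pure-noise feature passes the p<=0.1 screen ~10% of the time."""
        rng = np.random.default_rng(99)
        n, reps = 500, 1000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        kept = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            kept += len(univariate_screen(_df(x[:, None]), y, 0.1))
        assert abs(kept / reps - 0.1) < 0.03


class TestBackwardElimination:
    def test_noise_removed_signal_kept(self):
        """The strong signal always survives; the pure-noise feature is
        dropped at the AIC's intrinsic rate (it survives only when its
        deviance contribution exceeds 2, ~16% of draws)."""
        signal_kept = noise_removed = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 1000
            x_sig = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * x_sig))).astype(int)
            X = _df(np.column_stack([x_sig, rng.normal(size=n)]))
            result = aic_backward_eliminate(X, y)
            signal_kept += "F0" in result
            noise_removed += "F1" not in result
        assert signal_kept == n_seeds
        assert noise_removed >= 0.6 * n_seeds

    def test_pure_noise_single_feature_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        X = _df(rng.normal(size=(500, 1)))
        y = (rng.random(500) < 0.5).astype(int)
        assert aic_backward_eliminate(X, y) == []

    def test_matches_greedy_oracle_on_all_backward_paths(self, rng):
        """The greedy result's AIC equals an independent enumeration of
        the greedy backward path over all 2^5 subsets."""
        n, k = 200, 5
        X = rng.normal(size=(n, k))
        beta = np.array([1.2, 0.8, 0.0, 0.0, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        df = _df(X)

        aic_cache = {}

        def aic_of(subset):
            if subset not in aic_cache:
                if subset:
                    aic_cache[subset] = fit_logistic(df[list(subset)], y).aic
                else:
                    p = y.mean()
                    llf = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
                    aic_cache[subset] = 2 - 2 * llf
            return aic_cache[subset]

        # independent greedy oracle by exhaustive one-step lookahead
        current = tuple(df.columns)
        while current:
            options = [tuple(f for f in current if f != drop) for drop in current]
            best = min(options, key=aic_of)
            if aic_of(best) < aic_of(current) - 1e-10:
                current = best
            else:
                break
        result = tuple(aic_backward_eliminate(df, y))
        assert aic_of(result) == pytest.approx(aic_of(current), abs=1e-6)
        assert set(result) == set(current)
        # returned set's AIC <= any set reachable by one further removal
        for drop in result:
            reachable = tuple(f for f in result if f != drop)
            assert aic_of(result) <= aic_of(reachable) + 1e-10


class TestMultivariablePrune:
    def test_fixed_point_when_all_significant(self, rng):
        n = 400
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-(1.5 * X[:, 0] + 1.5 * X[:, 1])))).astype(int)
        df = _df(X)
        assert multivariable_prune(df, y, ["F0", "F1"], 0.1) == ["F0", "F1"]

    def test_signal_survives_correlated_noise(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 600
            sig = rng.normal(size=n)
            noise = sig[:, None] * 0.5 + rng.normal(size=(n, 3))
            y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * sig))).astype(int)
            df = _df(np.column_stack([sig, noise]))
            result = multivariable_prune(df, y, list(df.columns), 0.1)
            hits += "F0" in result
        assert hits >= 0.9 * n_seeds

    def test_tiny_alpha_empties_the_set(self, rng):
        X = _df(rng.normal(size=(80, 3)))
        y = (rng.random(80) < 0.5).astype(int)
        assert multivariable_prune(X, y, list(X.columns), 1e-12) == []


class TestEnsemble:
    def test_partition_property_and_cardinality(self, rng):
        n = 60
        X = _df(rng.normal(size=(n, 4)))
        X.index = [f"S{i}" for i in range(n)]
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        cfg = SelectionConfig(rounds=1, k_folds=2, seed=5)
        models = run_selection_ensemble(X, y, cfg)
        assert len(models) == 2
        union = set(models[0].test_ids) | set(models[1].test_ids)
        assert union == set(X.index)
        assert not set(models[0].test_ids) & set(models[1].test_ids)

    def test_deterministic_for_fixed_seed(self, rng):
        n = 80
        X = _df(rng.normal(size=(n, 6)))
        y = (np.arange(n) % 2).astype(int)
        cfg = SelectionConfig(rounds=2, k_folds=4, seed=11)
        a = run_selection_ensemble(X, y, cfg)
        b = run_selection_ensemble(X, y, cfg)
        assert [m.features for m in a] == [m.features for m in b]
        assert [m.test_auc for m in a] == [m.test_auc for m in b]


class TestRecurrenceRanking:
    def _stub(self, features, auc, p=None):
        return CandidateModel(0, 0, tuple(features), auc, 0.0, (), p or {})

    def test_counting_order(self):
        models = [self._stub(s, 0.8) for s in [("A", "B"), ("A", "C"), ("A",)]]
        cfg = SelectionConfig(top_model_fraction=1.0, top_n_recurring=30)
        ranked, counts = rank_by_recurrence(models, cfg)
        assert ranked[0] == "A" and counts["A"] == 3

    def test_top_fraction_of_100_models_uses_75(self):
        # 25 models retain X (low AUC), 75 retain Y (high AUC): with the
        # 75% cut only the Y-voters count
        models = [self._stub(("X",), 0.5) for _ in range(25)]
        models += [self._stub(("Y",), 0.9) for _ in range(75)]
        cfg = SelectionConfig(top_model_fraction=0.75, top_n_recurring=30)
        ranked, counts = rank_by_recurrence(models, cfg)
        assert counts["Y"] == 75 and "X" not in counts

    def test_tie_breaks_by_mean_univariate_p_then_id(self):
        models = [
            self._stub(("B",), 0.8, {"B": 0.01}),
            self._stub(("C",), 0.8, {"C": 0.05}),
            self._stub(("D",), 0.8, {"D": 0.01}),
            self._stub(("A",), 0.8, {"A": 0.01}),
        ]
        cfg = SelectionConfig(top_model_fraction=1.0, top_n_recurring=30)
        ranked, _ = rank_by_recurrence(models, cfg)
        assert ranked == ["A", "B", "D", "C"]


class TestAicNadir:
    def test_argmin_of_stubbed_sequence(self, monkeypatch):
        seq = iter([100.0, 90.0, 85.0, 88.0, 92.0])

        class _Fit:
            def __init__(self):
                self.aic = next(seq)

        monkeypatch.setattr(selmod, "fit_logistic", lambda X, y: _Fit())
        X = pd.DataFrame(np.zeros((10, 5)), columns=list("abcde"))
        panel = select_panel_size_aic_nadir(X, np.zeros(10), list("abcde"), 5)
        assert panel.panel_size == 3
        assert panel.panel == ("a", "b", "c")

    def test_monotone_decreasing_sequence_uses_max_panel(self, monkeypatch):
        seq = iter([50.0, 40.0, 30.0, 20.0])

        class _Fit:
            def __init__(self):
                self.aic = next(seq)

        monkeypatch.setattr(selmod, "fit_logistic", lambda X, y: _Fit())
        X = pd.DataFrame(np.zeros((10, 4)), columns=list("abcd"))
        panel = select_panel_size_aic_nadir(X, np.zeros(10), list("abcd"), 4)
        assert panel.panel_size == 4

    def test_nadir_finds_planted_markers(self, rng):
        """With 3 strong markers ahead of noise in the ranking, the
        nadir lands near 3."""
        n = 600
        X = rng.normal(size=(n, 10))
        beta = np.zeros(10)
        beta[:3] = 1.2
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        df = _df(X)
        panel = select_panel_size_aic_nadir(df, y, list(df.columns), 10)
        assert 3 <= panel.panel_size <= 6
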