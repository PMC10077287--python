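"""Base learners, splits, pseudo-absences, AUC/TSS and interpretation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from aquasdm import (
    ALGORITHMS,
    auc_score,
    bootstrap_splits,
    evaluate,
    fit_model,
    response_curve,
    sample_pseudo_absences,
    tss_scan,
    variable_importance,
)
from aquasdm.models import build_training_table

from .conftest import make_separable_table, random_stack


class TestPseudoAbsences:
    def test_excludes_presence_cells(self):
        stack = random_stack(0)
        frame = stack.to_frame()
        presence_cells = frame.index[:30].to_numpy()
        rng = np.random.default_rng(1)
        bg, capped = sample_pseudo_absences(stack, presence_cells, 50, rng)
        assert not capped
        assert len(bg) == 50
        assert not set(bg["cell"]) & set(presence_cells)
        assert bg["cell"].is_unique

    def test_cap_and_warning(self):
        stack = random_stack(0)
        frame = stack.to_frame()
        presence_cells = frame.index[:5].to_numpy()
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="capped"):
            bg, capped = sample_pseudo_absences(stack, presence_cells, 10_000, rng)
        assert capped
        assert len(bg) == len(frame) - 5

    def test_values_come_from_cells(self):
        stack = random_stack(0)
        rng = np.random.default_rng(2)
        bg, _ = sample_pseudo_absences(stack, [0], 20, rng)
        for _, row in bg.iterrows():
            i, j = divmod(int(row["cell"]), stack.spec.nlon)
            assert row["SBT"] == stack.variables["SBT"][i, j]


class TestSplits:
    def test_exact_partition_and_stratification(self):
        table = make_separable_table(100)
        splits = bootstrap_splits(table, 0.75, 10, seed=0)
        assert len(splits) == 10
        y = table["label"].to_numpy()
        for tr, te in splits:
            assert len(tr) == 75 and len(te) == 25
            assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(100))
            for part in (tr, te):
                assert len(np.unique(y[part])) == 2

    def test_replicates_differ(self):
        table = make_separable_table(100)
        splits = bootstrap_splits(table, 0.75, 5, seed=0)
        trains = {tuple(tr) for tr, _ in splits}
        assert len(trains) > 1

    def test_single_class_raises(self):
        table = make_separable_table(40)
        table["label"] = 1
        with pytest.raises(ValueError):
            bootstrap_splits(table)


class TestAucTss:
    def test_spec_worked_example(self):
        # pos {0.9, 0.6, 0.4}, neg {0.7, 0.3, 0.1}: 7 of 9 pairs concordant
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.6, 0.4, 0.7, 0.3, 0.1])
        assert auc_score(y, s) == pytest.approx(7.0 / 9.0)
        tss, thr, _ = tss_scan(y, s)
        assert tss == pytest.approx(2.0 / 3.0)

    def test_perfect_and_reverse(self):
        y = np.array([0, 0, 1, 1])
        assert auc_score(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auc_score(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0
        tss, _, counts = tss_scan(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert tss == 1.0 and counts == (2, 0, 2, 0)

    def test_ties_count_half(self):
        y = np.array([1, 0])
        s = np.array([0.5, 0.5])
        assert auc_score(y, s) == pytest.approx(0.5)

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_tss_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)
            tss, thr, (tp, fp, tn, fn) = tss_scan(y, s)
            best = max(
                ((s >= t) & (y == 1)).sum() / (y == 1).sum()
                + (~(s >= t) & (y == 0)).sum() / (y == 0).sum()
                - 1.0
                for t in np.unique(s)
            )
            assert tss == pytest.approx(best, abs=1e-9)
            # the returned threshold attains the maximum
            sens = ((s >= thr) & (y == 1)).sum() / (y == 1).sum()
            spec = (~(s >= thr) & (y == 0)).sum() / (y == 0).sum()
            assert sens + spec - 1.0 == pytest.approx(best, abs=1e-9)
            assert tp + fn == (y == 1).sum() and fp + tn == (y == 0).sum()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_score(np.ones(3), np.random.rand(3))
        with pytest.raises(ValueError):
            tss_scan(np.zeros(3), np.random.rand(3))


class TestFitEvaluate:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_each_algorithm_learns_separable_data(self, algo):
        table = make_separable_table(160, seed=3)
        splits = bootstrap_splits(table, 0.75, 1, seed=0)
        tr, te = splits[0]
        model = fit_model(algo, table.iloc[tr], seed=0)
        ev = evaluate(model, table.iloc[te])
        assert ev.auc > 0.9
        assert ev.tss > 0.7
        probs = model.predict_probability(table.iloc[te])
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_determinism(self):
        table = make_separable_table(80, seed=5)
        for algo in ("RF", "BRT"):
            a = fit_model(algo, table, seed=9).predict_probability(table)
            b = fit_model(algo, table, seed=9).predict_probability(table)
            assert np.array_equal(a, b)

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_model("GLM", make_separable_table(40))

    def test_single_class_raises(self):
        table = make_separable_table(40)
        table["label"] = 0
        with pytest.raises(ValueError):
            fit_model("RF", table)

    def test_predict_stack_propagates_nan(self):
        table = make_separable_table(80)
        model = fit_model("RF", table, seed=0)
        stack = random_stack(4)
        field = model.predict_stack(stack)
        assert np.isnan(field[~stack.mask]).all()
        assert np.isfinite(field[stack.mask]).all()

    def test_build_training_table_rejects_nan(self):
        pres = make_separable_table(20).drop(columns="label")
        bg = make_separable_table(20)
        bg["label"] = 0
        pres.loc[0, "SBT"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_training_table(pres, bg)


class TestInterpretation:
    def test_importance_finds_the_driver(self):
        table = make_separable_table(200, seed=7)
        model = fit_model("RF", table, seed=0)
        imp = variable_importance(model, table, seed=0)
        assert imp.idxmax() == "SBT"
        assert imp["SBT"] > 2 * max(imp["SST"], imp["SSS"], imp["SBS"])
        assert ((imp >= 0) & (imp <= 1)).all()

    def test_importance_needs_rows(self):
        table = make_separable_table(200)
        model = fit_model("RF", table.iloc[::4], seed=0)  # subset with both classes
        with pytest.raises(ValueError):
            variable_importance(model, table.iloc[:10])

    def test_response_curve_peaks_in_presence_range(self):
        table = make_separable_table(200, seed=8)
        model = fit_model("RF", table, seed=0)
        curve = response_curve(model, "SBT")
        assert len(curve) == 100
        peak = curve.loc[curve["probability"].idxmax(), "value"]
        assert 3.0 <= peak <= 16.0  # presences were drawn at SBT ~ N(10, 2)
        assert curve["value"].iloc[0] == pytest.approx(table["SBT"].min())
        assert curve["value"].iloc[-1] == pytest.approx(table["SBT"].max())

    def test_response_curve_unknown_variable(self):
        model = fit_model("RF", make_separable_table(60), seed=0)
        with pytest.raises(ValueError):
            response_curve(model, "depth")
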