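"""Wilcoxon elimination, subset assembly, SVM scoring and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegstress import (
    FEATURE_COLUMNS,
    ClassifierSpec,
    ConfusionCounts,
    SubsetSpec,
    assemble_subset,
    channel_band_sweep,
    fit_and_score,
    performance_metrics,
    wilcoxon_filter,
)
from eegstress.classify import stratified_split, subset_slices

from conftest import synthetic_feature_table


def table_of(values_by_col, n=20, seed=0):
    rng = np.random.default_rng(seed)
    data = {c: rng.standard_normal(n) for c in FEATURE_COLUMNS}
    data.update(values_by_col)
    return pd.DataFrame(data)


class TestWilcoxonFilter:
    def test_identical_tables_eliminate_everything(self):
        a = table_of({}, n=20)
        retained, pvals = wilcoxon_filter(a, a.copy())
        assert retained == []
        assert all(p == 1.0 for p in pvals.values())

    def test_large_shift_retains_only_shifted_column(self):
        a = table_of({}, n=20, seed=1)
        b = a.copy()
        b["activity"] = a["activity"] + 10.0  # +10 sigma shift
        retained, pvals = wilcoxon_filter(a, b)
        assert "activity" in retained
        assert pvals["activity"] < 0.05
        # exact two-sided p for 20 uniformly-shifted pairs: 2/2^20
        assert pvals["activity"] == pytest.approx(2 / 2 ** 20, rel=1e-6)

    def test_five_pairs_cannot_reach_significance(self):
        # all-positive differences at n=5: exact two-sided p = 2/32 = 0.0625
        a = table_of({}, n=5, seed=2)
        b = a - 1.0
        retained, pvals = wilcoxon_filter(a, b)
        assert retained == []
        for p in pvals.values():
            assert p == pytest.approx(0.0625)

    def test_unpaired_slices_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            wilcoxon_filter(table_of({}, n=10), table_of({}, n=12))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wilcoxon_filter(table_of({}, n=4), table_of({}, n=4))


class TestAssembleSubset:
    def test_male_vs_female_counts(self, feature_table):
        X, y = assemble_subset(
            feature_table, SubsetSpec("male_vs_female", "MI-1", "C3", "delta")
        )
        assert int(y.sum()) == 9 * 4
        assert int((y == 0).sum()) == 9 * 4
        assert X.shape == (72, 8)

    def test_baseline_subset_pairs_same_group(self, feature_table):
        pos, neg = subset_slices(
            feature_table, SubsetSpec("baseline_vs_male", "MI-1", "C4", "alpha")
        )
        assert set(pos["group"]) == {"male"} == set(neg["group"])
        assert set(pos["condition"]) == {"MI-1"}
        assert set(neg["condition"]) == {"baseline"}
        assert list(pos["subject_id"]) == list(neg["subject_id"])
        assert list(pos["window"]) == list(neg["window"])

    def test_absent_channel_rejected(self, feature_table):
        with pytest.raises(ValueError, match="channel"):
            assemble_subset(
                feature_table, SubsetSpec("male_vs_female", "MI-1", "O1",
                                          "delta")
            )

    def test_unknown_subset_name_rejected(self):
        with pytest.raises(ValueError):
            SubsetSpec("males_only", "MI-1", "C3", "delta")


class TestFitAndScore:
    def test_separable_classes_score_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 1)), rng.normal(8, 1, (40, 1))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        counts, metrics = fit_and_score(X, y, ClassifierSpec(seed=0))
        assert metrics.accuracy == 100.0
        assert counts.total == 16  # 20% of 80 held out

    def test_permuted_labels_score_at_chance(self, rng):
        accs = []
        for i in range(50):
            X = rng.standard_normal((500, 8))
            y = np.r_[np.ones(250, int), np.zeros(250, int)]
            rng.shuffle(y)
            _, m = fit_and_score(X, y, ClassifierSpec(seed=i))
            accs.append(m.accuracy)
        assert np.mean(accs) == pytest.approx(50.0, abs=7.0)

    def test_split_is_stratified_and_partitions_rows(self, rng):
        X = np.arange(100, dtype=float).reshape(-1, 1)
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        X_tr, X_te, y_tr, y_te = stratified_split(X, y, 0.8, seed=0)
        assert len(X_tr) == 80 and len(X_te) == 20
        assert sorted(np.r_[X_tr[:, 0], X_te[:, 0]].tolist()) == list(
            map(float, range(100))
        )
        assert y_tr.sum() == 40 and y_te.sum() == 10

    def test_eight_two_split_of_pooled_table(self):
        # 2,560 pooled windows split 8:2 -> 2,048 train / 512 test
        X = np.zeros((2560, 1))
        y = np.r_[np.ones(1280, int), np.zeros(1280, int)]
        X_tr, X_te, _, _ = stratified_split(X, y, 0.8, seed=0)
        assert len(X_tr) == 2048 and len(X_te) == 512

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="class"):
            fit_and_score(X, np.ones(10, int))

    def test_tiny_class_split_error_mentions_seed_or_rows(self):
        X = np.zeros((6, 2))
        y = np.r_[np.ones(5, int), np.zeros(1, int)]
        with pytest.raises(ValueError):
            fit_and_score(X, y)


class TestPerformanceMetrics:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,sen,spe,acc",
        [
            (5, 0, 5, 0, 100.0, 100.0, 100.0),
            (3, 2, 2, 1, 75.0, 50.0, 62.5),
            (0, 0, 4, 0, None, 100.0, 100.0),
        ],
    )
    def test_formula_cases(self, tp, fp, tn, fn, sen, spe, acc):
        m = performance_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert m.sensitivity == sen
        assert m.specificity == spe
        assert m.accuracy == acc

    def test_matches_brute_force_recount(self, rng):
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        c = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (y == 1))),
            fp=int(np.sum((pred == 1) & (y == 0))),
            tn=int(np.sum((pred == 0) & (y == 0))),
            fn=int(np.sum((pred == 0) & (y == 1))),
        )
        m = performance_metrics(c)
        assert m.accuracy == pytest.approx(100.0 * np.mean(pred == y))

    @given(
        tp=st.integers(0, 5), fp=st.integers(0, 5),
        tn=st.integers(0, 5), fn=st.integers(0, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_label_swap_symmetry(self, tp, fp, tn, fn):
        """Swapping class labels swaps Sen and Spec, keeps accuracy."""
        if tp + fp + tn + fn == 0:
            return
        m = performance_metrics(ConfusionCounts(tp, fp, tn, fn))
        m_sw = performance_metrics(ConfusionCounts(tn, fn, tp, fp))
        assert m_sw.sensitivity == m.specificity
        assert m_sw.specificity == m.sensitivity
        assert m_sw.accuracy == m.accuracy
        for v in (m.sensitivity, m.specificity):
            if v is not None:
                assert 0.0 <= v <= 100.0


class TestChannelBandSweep:
    def test_cell_grid_is_complete(self, feature_table):
        sweep = channel_band_sweep(
            feature_table, interventions=("MI-1",),
            channels=("C3", "C4"), bands=("delta", "alpha"),
        )
        assert len(sweep) == 3 * 1 * 2 * 2

    def test_injected_effect_found_in_its_band(self):
        effect = {("male", "MI-1", "delta"): 6.0}
        table = synthetic_feature_table(effect=effect, seed=11)
        sweep = channel_band_sweep(table, interventions=("MI-1",))
        ok = sweep[sweep["skip_reason"] == ""]
        mvf = ok[ok["subset"] == "male_vs_female"]
        best = mvf.loc[mvf["accuracy"].idxmax()]
        assert best["band"] == "delta"
        assert best["accuracy"] >= 90.0

    def test_null_table_mostly_skipped_or_chance(self):
        table = synthetic_feature_table(seed=21)
        sweep = channel_band_sweep(table, interventions=("MI-1",))
        scored = sweep[sweep["skip_reason"] == ""]
        skipped = sweep[sweep["skip_reason"] != ""]
        assert len(skipped) > 0  # Wilcoxon eliminates everything in most cells
        if len(scored):
            assert scored["accuracy"].mean() < 80.0

    def test_sweep_is_reproducible(self, feature_table):
        kw = dict(interventions=("MI-1",), channels=("C3",),
                  bands=("delta",), apply_filter=False)
        s1 = channel_band_sweep(feature_table, **kw)
        s2 = channel_band_sweep(feature_table, **kw)
        pd.testing.assert_frame_equal(s1, s2)
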