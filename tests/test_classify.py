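"""Tests of Fisher LDA, threshold selection, confusion metrics, ROC/AUC
and patient-grouped cross-validation."""
import numpy as np
import pandas as pd
import pytest

from octspeckle import (DEFAULT_COMBINATIONS, confusion_metrics,
                        evaluate_combinations, fisher_criterion, fisher_lda,
                        grouped_kfold_cv, roc_auc, select_threshold)
from octspeckle.core import (ConfigurationError, DegenerateModelError,
                             ParameterError, UndefinedMetricError)


def threshold_oracle(proj, pos):
    """Exhaustive scan of every candidate threshold (same candidate set
    and tie rule as the implementation, evaluated by plain loops)."""
    proj = np.asarray(proj, float)
    pos = np.asarray(pos, bool)
    uniq = np.unique(proj)
    span = uniq[-1] - uniq[0]
    delta = span if span > 0 else 1.0
    cands = [uniq[0] - delta / 2]
    cands += [(uniq[i] + uniq[i + 1]) / 2 for i in range(len(uniq) - 1)]
    cands += [uniq[-1] + delta / 2]
    best, best_score = [], -np.inf
    for c in cands:
        se = np.mean(proj[pos] > c)
        sp = np.mean(proj[~pos] <= c)
        if se + sp > best_score + 1e-15:
            best, best_score = [c], se + sp
        elif abs(se + sp - best_score) <= 1e-15:
            best.append(c)
    center = (np.median(proj[pos]) + np.median(proj[~pos])) / 2
    return min(best, key=lambda c: abs(c - center))


def auc_pair_count_oracle(proj, pos):
    """AUC as the normalized Mann-Whitney pair count (ties worth 1/2)."""
    p, n = proj[pos], proj[~pos]
    wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in p for ni in n)
    return wins / (len(p) * len(n))


class TestFisherLDA:
    def test_1d_reduces_to_feature(self, rng):
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(5, 1, 20)
        m = fisher_lda(x1, x2)
        assert m.w.shape == (1,)
        assert m.w[0] == pytest.approx(1.0)  # oriented toward class 2

    def test_2d_symmetric_clouds(self, rng):
        x1 = rng.normal(0, 1, (200, 2))
        x2 = rng.normal(0, 1, (200, 2)) + np.array([3.0, 0.0])
        m = fisher_lda(x1, x2)
        assert abs(m.w[0]) > 0.99  # w essentially along the mean gap
        assert np.linalg.norm(m.w) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,dim", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_maximizes_fisher_criterion(self, seed, dim):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0, 1, (15, dim)) @ rng.random((dim, dim))
        x2 = rng.normal(0.8, 1.2, (12, dim))
        m = fisher_lda(x1, x2)
        j_star = fisher_criterion(m.w, x1, x2)
        dirs = rng.standard_normal((1000, dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for v in dirs:
            assert j_star >= fisher_criterion(v, x1, x2) - 1e-9 * j_star

    def test_sklearn_direction_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        x1 = rng.normal(0, 1, (30, 3))
        x2 = rng.normal(1, 1.5, (25, 3))
        m = fisher_lda(x1, x2)
        lda = sklearn.LinearDiscriminantAnalysis(solver="eigen")
        lda.fit(np.vstack([x1, x2]), np.r_[np.zeros(30), np.ones(25)])
        v = lda.coef_.ravel()
        v = v / np.linalg.norm(v)
        cos = abs(v @ m.w)
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_means(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [1.0, 1.0]])
        with pytest.raises(DegenerateModelError):
            fisher_lda(x, x.copy())

    def test_singular_scatter_ridge_escalation(self):
        # both features identical: S_W singular, ridge must rescue
        x1 = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        x2 = x1 + 5.0
        m = fisher_lda(x1, x2)
        assert np.all(np.isfinite(m.w))
        assert m.ridge > 0

    def test_affine_feature_rescale_preserves_ordering(self, rng):
        x1 = rng.normal(0, 1, (20, 2))
        x2 = rng.normal(2, 1, (20, 2))
        m = fisher_lda(x1, x2)
        scale = np.array([100.0, 0.01])
        m2 = fisher_lda(x1 * scale, x2 * scale)
        p_ref = np.argsort(m.project(np.vstack([x1, x2])))
        p_new = np.argsort(m2.project(np.vstack([x1, x2]) * scale))
        assert np.array_equal(p_ref, p_new)


class TestSelectThreshold:
    def test_perfect_separation(self):
        proj = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        pos = np.array([False, False, False, True, True, True])
        thr = select_threshold(proj, pos)
        se = np.mean(proj[pos] > thr)
        sp = np.mean(proj[~pos] <= thr)
        assert se + sp == pytest.approx(2.0)
        assert 0.2 < thr < 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        proj = np.round(rng.normal(0, 1, 40), 2)  # rounding forces ties
        pos = rng.random(40) < 0.5
        if pos.all() or (~pos).all():
            pos[0] = not pos[0]
        assert select_threshold(proj, pos) == pytest.approx(
            threshold_oracle(proj, pos))

    def test_identical_distributions_near_chance(self):
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            proj = rng.normal(0, 1, 60)
            pos = np.r_[np.zeros(30, bool), np.ones(30, bool)]
            thr = select_threshold(proj, pos)
            se = np.mean(proj[pos] > thr)
            sp = np.mean(proj[~pos] <= thr)
            scores.append(se + sp)
        # on held-in data the optimum sits slightly above chance
        assert 1.0 <= np.mean(scores) < 1.5

    def test_single_class_error(self):
        with pytest.raises(ParameterError):
            select_threshold(np.arange(5.0), np.ones(5, bool))


class TestConfusionMetrics:
    def test_formula_evaluation(self):
        m = confusion_metrics(tp=9, tn=8, fp=2, fn=1)
        assert m.se == pytest.approx(0.9)
        assert m.sp == pytest.approx(0.8)
        assert m.pr == pytest.approx(9 / 11)
        assert m.undefined == ()

    def test_perfect_precision_limit(self):
        m = confusion_metrics(tp=5, tn=3, fp=0, fn=2)
        assert m.pr == 1.0

    def test_degenerate_denominators_flagged(self):
        m = confusion_metrics(tp=0, tn=4, fp=0, fn=0)
        assert m.se is None and "se" in m.undefined
        assert m.pr is None and "pr" in m.undefined
        assert m.sp == 1.0

    def test_all_zero_error(self):
        with pytest.raises(UndefinedMetricError):
            confusion_metrics(0, 0, 0, 0)

    def test_negative_count_error(self):
        with pytest.raises(ParameterError):
            confusion_metrics(-1, 0, 0, 1)


class TestROCAUC:
    def test_perfect_separation(self):
        proj = np.array([0.0, 0.1, 0.9, 1.0])
        pos = np.array([False, False, True, True])
        pts, auc = roc_auc(proj, pos)
        assert auc == pytest.approx(1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_shuffled_labels_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            proj = rng.normal(0, 1, 80)
            pos = rng.permutation(np.r_[np.zeros(40, bool), np.ones(40, bool)])
            aucs.append(roc_auc(proj, pos)[1])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        proj = np.round(rng.normal(0, 1, 50), 1)  # ties present
        pos = rng.random(50) < 0.4
        if pos.all() or (~pos).all():
            pos[0] = not pos[0]
        _, auc = roc_auc(proj, pos)
        assert auc == pytest.approx(auc_pair_count_oracle(proj, pos),
                                    rel=1e-12)

    def test_sklearn_cross_check(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        proj = rng.normal(0, 1, 60)
        pos = rng.random(60) < 0.5
        pos[:2] = [True, False]
        _, auc = roc_auc(proj, pos)
        assert auc == pytest.approx(metrics.roc_auc_score(pos, proj))

    def test_label_flip_identity(self, rng):
        proj = rng.normal(0, 1, 40)
        pos = rng.random(40) < 0.5
        pos[:2] = [True, False]
        _, a1 = roc_auc(proj, pos)
        _, a2 = roc_auc(proj, ~pos)
        assert a1 + a2 == pytest.approx(1.0)


def _feature_frame(rng, n_patients=4, n_scans=3, gap=3.0):
    """Synthetic feature table: two classes of patients with per-patient
    random effects, no images involved."""
    rows = []
    for label, mean in (("neg", 0.0), ("pos", gap)):
        for p in range(n_patients):
            p_eff = rng.normal(0, 0.5, 2)
            for s in range(n_scans):
                x = mean + p_eff + rng.normal(0, 0.5, 2)
                rows.append({"label": label, "patient_id": f"{label}{p}",
                             "scan_id": f"{label}{p}s{s}",
                             "mu": x[0], "p1": x[1]})
    return pd.DataFrame(rows)


class TestGroupedKFoldCV:
    def test_no_patient_straddles_folds(self, rng):
        df = _feature_frame(rng)
        res = grouped_kfold_cv(df, ("mu", "p1"), positive_label="pos")
        for fold in res.folds:
            assert not set(fold.train_patients) & set(fold.test_patients)

    def test_k_max_is_limiting_class_patient_count(self, rng):
        df = _feature_frame(rng, n_patients=5)
        df = df[~((df.label == "neg") & (df.patient_id == "neg4"))]
        res = grouped_kfold_cv(df, ("mu",), k="max", positive_label="pos")
        assert res.k == 4

    def test_separable_classes_perfect_metrics(self, rng):
        df = _feature_frame(rng, gap=50.0)
        res = grouped_kfold_cv(df, ("mu", "p1"), positive_label="pos")
        assert res.se == 1.0 and res.sp == 1.0
        assert res.auc == 1.0

    def test_metrics_within_unit_interval(self, rng):
        df = _feature_frame(rng, gap=0.5)
        res = grouped_kfold_cv(df, ("mu",), positive_label="pos")
        for v in (res.se, res.sp, res.pr, res.auc):
            assert 0.0 <= v <= 1.0
        assert "Fisher LDA" in res.summary()

    def test_unknown_feature_error(self, rng):
        with pytest.raises(ConfigurationError):
            grouped_kfold_cv(_feature_frame(rng), ("bogus",))

    def test_single_patient_class_error(self, rng):
        df = _feature_frame(rng)
        df = df[df.patient_id.isin(["neg0", "pos0", "pos1"])]
        with pytest.raises(ParameterError):
            grouped_kfold_cv(df, ("mu",), positive_label="pos")


class TestEvaluateCombinations:
    def test_default_list_has_15_entries(self):
        assert len(DEFAULT_COMBINATIONS) == 15
        # singles, dispersion pairs, mixtures, speckle-only sets
        assert ("mu",) in DEFAULT_COMBINATIONS
        assert ("mu", "p1", "p2") in DEFAULT_COMBINATIONS
        assert ("p1", "sigma_p1", "p2", "sigma_p2") in DEFAULT_COMBINATIONS

    def test_one_pair_yields_15_rows(self, rng):
        df = _feature_frame(rng)
        for c in ("sigma_mu", "p2", "sigma_p1", "sigma_p2"):
            df[c] = rng.normal(0, 1, len(df))
        table = evaluate_combinations(df)
        assert len(table) == 15
        assert table["best"].sum() == 1

    def test_unknown_feature_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            evaluate_combinations(_feature_frame(rng), [("mu", "nope")])
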