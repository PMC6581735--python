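import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdconnectome import (
    AdjacencyMatrix,
    ConfusionMatrix,
    FeatureSpec,
    MaskFamily,
    SvmConfig,
    loocv_evaluate,
    metrics_from_confusion,
    roc_auc,
)
from tests.conftest import FAST_SVM


def auc_pairwise_oracle(scores, labels):
    """Mean over all (positive, negative) pairs; ties earn half credit."""
    pos = [s for s, l in zip(scores, labels) if l == "SD"]
    neg = [s for s, l in zip(scores, labels) if l == "HC"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetricsFromConfusion:
    @pytest.mark.parametrize(
        "cm, acc, sens, spec",
        [
            # top-ranked region models' confusion matrices
            (ConfusionMatrix(tn=37, fp=3, fn=3, tp=31), 68 / 74, 31 / 34, 37 / 40),
            (ConfusionMatrix(tn=36, fp=4, fn=2, tp=32), 68 / 74, 32 / 34, 36 / 40),
            (ConfusionMatrix(tn=38, fp=2, fn=5, tp=29), 67 / 74, 29 / 34, 38 / 40),
            (ConfusionMatrix(tn=5, fp=0, fn=0, tp=7), 1.0, 1.0, 1.0),
        ],
    )
    def test_formulas(self, cm, acc, sens, spec):
        a, s, sp = metrics_from_confusion(cm)
        assert (a, s, sp) == pytest.approx((acc, sens, spec))

    def test_empty_class_fails(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(tn=3, fp=1, fn=0, tp=0))


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], ["HC", "HC", "SD", "SD"])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, ["HC", "SD"] * 3)
        assert auc == 0.5

    def test_hand_counted_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], ["HC", "HC", "SD", "SD"])
        assert auc == 0.75

    def test_single_class_fails(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["SD", "SD"])

    def test_curve_is_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(30)
        labels = ["SD" if k % 3 else "HC" for k in range(30)]
        points, _ = roc_auc(scores, labels)
        xs, ys = zip(*points)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=30),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_pairwise_oracle(self, raw, seed):
        rng = np.random.default_rng(seed)
        labels = ["SD" if rng.random() < 0.5 else "HC" for _ in raw]
        if len(set(labels)) < 2:
            labels[0], labels[1] = "SD", "HC"
        scores = [float(x) for x in raw]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pairwise_oracle(scores, labels))


def _separable_cohort(margin=0.3):
    """6 subjects, 3 nodes; edge (0,1) separates groups with a clear margin."""
    adjs, groups = [], []
    for k, (w, g) in enumerate(
        [(0.1, "SD"), (0.15, "SD"), (0.2, "SD"),
         (0.2 + margin, "HC"), (0.25 + margin, "HC"), (0.3 + margin, "HC")]
    ):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = w
        W[1, 2] = W[2, 1] = 0.5 + 0.01 * k  # uninformative varying edge
        adjs.append(AdjacencyMatrix(f"s{k}", W, list("abc")))
        groups.append(g)
    mask = np.zeros((3, 3), dtype=bool)
    mask[0, 1] = mask[1, 0] = mask[1, 2] = mask[2, 1] = True
    fam = MaskFamily(mask, [mask.copy() for _ in adjs], alpha=0.05)
    return adjs, groups, fam


class TestLoocvEvaluate:
    CFG = SvmConfig(C_grid=(1.0, 100.0), gamma_grid=(0.5, 2.0), inner_cv_folds=2, seed=0)

    def test_separable_toy_cohort_is_perfect(self):
        adjs, groups, fam = _separable_cohort()
        spec = FeatureSpec("toy", (0, 1), scope="incident")
        rep = loocv_evaluate(spec, fam, adjs, groups, self.CFG)
        cm = rep.confusion
        assert (cm.tn, cm.fp, cm.fn, cm.tp) == (3, 0, 0, 3)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_strongly_planted_cohort_is_perfect(self, planted_small, planted_small_masks, toy_parcellation):
        from sdconnectome import anatomical_feature_specs

        _, _, _, adjs, groups = planted_small
        spec = [s for s in anatomical_feature_specs(toy_parcellation) if s.name == "R1"][0]
        rep = loocv_evaluate(spec, planted_small_masks, adjs, groups, FAST_SVM)
        assert rep.accuracy >= 0.9
        assert rep.auc >= 0.95

    def test_reported_metrics_equal_confusion_recomputation(self, planted_small, planted_small_masks, toy_parcellation):
        from sdconnectome import anatomical_feature_specs

        _, _, _, adjs, groups = planted_small
        spec = anatomical_feature_specs(toy_parcellation)[1]
        rep = loocv_evaluate(spec, planted_small_masks, adjs, groups, FAST_SVM)
        acc, sens, spc = metrics_from_confusion(rep.confusion)
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == (acc, sens, spc)
        # pooled-decision AUC equals the pairwise oracle
        assert rep.auc == pytest.approx(
            auc_pairwise_oracle(rep.decision_values, groups)
        )

    def test_deterministic_given_seed(self):
        adjs, groups, fam = _separable_cohort()
        spec = FeatureSpec("toy", (0, 1, 2), scope="incident")
        r1 = loocv_evaluate(spec, fam, adjs, groups, self.CFG)
        r2 = loocv_evaluate(spec, fam, adjs, groups, self.CFG)
        assert r1.to_dict() == r2.to_dict()

    def test_empty_feature_fold_falls_back_to_majority(self):
        adjs, groups, fam = _separable_cohort()
        empty = np.zeros((3, 3), dtype=bool)
        fam_empty = MaskFamily(empty, [empty.copy() for _ in adjs], alpha=0.05)
        spec = FeatureSpec("toy", (0, 1), scope="incident")
        rep = loocv_evaluate(spec, fam_empty, adjs, groups, self.CFG)
        assert rep.n_features == [0] * 6
        assert all(np.isnan(c) for c, _ in rep.chosen_params)

    def test_grid_tie_break_prefers_smallest_c_then_gamma(self):
        # a duplicated grid value cannot beat the first (smallest) optimum
        adjs, groups, fam = _separable_cohort()
        spec = FeatureSpec("toy", (0, 1), scope="incident")
        cfg = SvmConfig(C_grid=(1.0, 1.0 + 1e-12), gamma_grid=(0.5, 0.5 + 1e-12),
                        inner_cv_folds=2, seed=0)
        rep = loocv_evaluate(spec, fam, adjs, groups, cfg)
        for C, gamma in rep.chosen_params:
            assert C == 1.0 and gamma == 0.5

    def test_global_search_and_standardize_modes(self):
        adjs, groups, fam = _separable_cohort()
        spec = FeatureSpec("toy", (0, 1), scope="incident")
        cfg = SvmConfig(C_grid=(1.0, 100.0), gamma_grid=(0.5, 2.0),
                        inner_cv_folds=2, seed=0, search="global", standardize=True)
        rep = loocv_evaluate(spec, fam, adjs, groups, cfg)
        # one globally tuned (C, gamma) shared by every fold
        assert len(set(rep.chosen_params)) == 1
        assert rep.accuracy == 1.0

    def test_mask_family_size_mismatch_fails(self):
        adjs, groups, fam = _separable_cohort()
        bad = MaskFamily(fam.full_mask, fam.fold_masks[:-1], alpha=0.05)
        spec = FeatureSpec("toy", (0, 1))
        with pytest.raises(ValueError, match="folds"):
            loocv_evaluate(spec, bad, adjs, groups, self.CFG)
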