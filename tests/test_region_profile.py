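import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdconnectome import (
    DegreeVector,
    accuracy_confounder_check,
    compare_subregion_degrees,
    edgewise_ttest,
    profile_regions,
    subsample_connections_experiment,
    uniform_parcellation,
)
from sdconnectome.features import FeatureSpec, feature_edges
from tests.conftest import FAST_SVM


@pytest.fixture(scope="module")
def small_stats(planted_small):
    _, _, _, adjs, groups = planted_small
    return edgewise_ttest(adjs, groups)


class TestProfileRegions:
    def test_counts_match_hand_enumeration_on_complete_mask(self, small_stats, toy_parcellation):
        n = 12
        mask = ~np.eye(n, dtype=bool)
        profiles = profile_regions(small_stats, mask, toy_parcellation, ["R1", "R2", "R3"])
        for p in profiles:
            nodes = set(toy_parcellation.nodes_of(p.name))
            expected = sum(
                1
                for i in range(n)
                for j in range(i + 1, n)
                if i in nodes or j in nodes
            )
            assert p.n_significant_connections == expected  # 4*8 + C(4,2) = 38
            assert sum(p.partner_counts.values()) == p.n_significant_connections

    def test_empty_mask_gives_zero_counts_and_missing_mean_p(self, small_stats, toy_parcellation):
        (p,) = profile_regions(small_stats, np.zeros((12, 12), bool), toy_parcellation, ["R1"])
        assert p.n_significant_connections == 0
        assert np.isnan(p.mean_p)
        assert p.partner_counts == {}

    def test_unknown_region_fails(self, small_stats, toy_parcellation):
        with pytest.raises(KeyError):
            profile_regions(small_stats, np.zeros((12, 12), bool), toy_parcellation, ["Nope"])

    def test_planted_region_has_most_connections(self, small_stats, toy_parcellation, planted_small_masks):
        profiles = profile_regions(
            small_stats, planted_small_masks.full_mask, toy_parcellation, ["R1", "R2", "R3"]
        )
        counts = {p.name: p.n_significant_connections for p in profiles}
        assert counts["R1"] == max(counts.values())

    def test_count_conservation(self, small_stats, toy_parcellation, planted_small_masks):
        # summing counts over all regions double-counts inter-region edges
        # and counts intra-region edges once
        mask = planted_small_masks.full_mask
        profiles = profile_regions(small_stats, mask, toy_parcellation, ["R1", "R2", "R3"])
        region_of = [toy_parcellation.merged_region_of[s] for s in toy_parcellation.subregion_labels]
        inter = intra = 0
        for i in range(12):
            for j in range(i + 1, 12):
                if mask[i, j]:
                    if region_of[i] == region_of[j]:
                        intra += 1
                    else:
                        inter += 1
        assert sum(p.n_significant_connections for p in profiles) == 2 * inter + intra

    def test_hemispheric_counts_reconcile_with_merged(self, small_stats, toy_parcellation, planted_small_masks):
        # L + R counts = merged count + cross-hemisphere within-region edges
        # (those are incident to both hemispheric subsets)
        mask = planted_small_masks.full_mask
        merged, left, right = profile_regions(
            small_stats, mask, toy_parcellation, ["R1", "R1_L", "R1_R"]
        )
        nodes_l = set(toy_parcellation.nodes_of("R1_L"))
        nodes_r = set(toy_parcellation.nodes_of("R1_R"))
        cross = sum(
            1
            for i in sorted(nodes_l | nodes_r)
            for j in sorted(nodes_l | nodes_r)
            if i < j and mask[i, j]
            and ((i in nodes_l) != (j in nodes_l))
        )
        assert (
            left.n_significant_connections + right.n_significant_connections
            == merged.n_significant_connections + cross
        )


class TestConfounderCheck:
    def _frame(self, acc, count, meanp):
        return pd.DataFrame(
            {"accuracy": acc, "n_significant_connections": count, "mean_p": meanp}
        )

    def test_perfectly_proportional_accuracy(self):
        cc = accuracy_confounder_check(self._frame([0.2, 0.4, 0.6], [1, 2, 3], [0.04, 0.03, 0.02]))
        assert cc.r_count == pytest.approx(1.0)
        # closed-form Pearson for x=(1,2,3), y=(2,4,6): r exactly 1
        r, _ = stats.pearsonr([1, 2, 3], [2, 4, 6])
        assert cc.r_count == pytest.approx(r)

    def test_independent_accuracy_gives_small_r(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(20):
            cc = accuracy_confounder_check(
                self._frame(rng.uniform(0.4, 1.0, 24), rng.integers(50, 240, 24),
                            rng.uniform(0.02, 0.04, 24))
            )
            rs.append(abs(cc.r_count))
        assert np.mean(rs) < 0.35

    def test_constant_accuracy_reported_missing(self):
        cc = accuracy_confounder_check(self._frame([0.5] * 4, [1, 2, 3, 4], [0.1] * 4))
        assert np.isnan(cc.r_count) and np.isnan(cc.p_count)

    def test_too_few_models_fails(self):
        with pytest.raises(ValueError):
            accuracy_confounder_check(self._frame([0.5, 0.6], [1, 2], [0.1, 0.2]))


class TestSubsampleConnections:
    def test_full_target_reproduces_unsubsampled_accuracy(self, planted_small, planted_small_masks, toy_parcellation):
        from sdconnectome import anatomical_feature_specs, loocv_evaluate

        _, _, _, adjs, groups = planted_small
        spec = [s for s in anatomical_feature_specs(toy_parcellation) if s.name == "R1"][0]
        full = loocv_evaluate(spec, planted_small_masks, adjs, groups, FAST_SVM)
        n_full = len(feature_edges(spec, planted_small_masks.full_mask))
        mean_acc, accs = subsample_connections_experiment(
            spec, planted_small_masks, adjs, groups, FAST_SVM,
            target_n=n_full, n_repeats=2, seed=0,
        )
        assert accs == [full.accuracy, full.accuracy]

    def test_single_connection_usually_worse(self, planted_small, planted_small_masks, toy_parcellation):
        from sdconnectome import anatomical_feature_specs, loocv_evaluate

        _, _, _, adjs, groups = planted_small
        spec = [s for s in anatomical_feature_specs(toy_parcellation) if s.name == "R1"][0]
        full = loocv_evaluate(spec, planted_small_masks, adjs, groups, FAST_SVM)
        _, accs = subsample_connections_experiment(
            spec, planted_small_masks, adjs, groups, FAST_SVM,
            target_n=1, n_repeats=10, seed=1,
        )
        assert np.mean([a <= full.accuracy for a in accs]) >= 0.9

    def test_fixed_seed_is_bit_identical(self, planted_small, planted_small_masks, toy_parcellation):
        from sdconnectome import anatomical_feature_specs

        _, _, _, adjs, groups = planted_small
        spec = [s for s in anatomical_feature_specs(toy_parcellation) if s.name == "R2"][0]
        runs = [
            subsample_connections_experiment(
                spec, planted_small_masks, adjs, groups, FAST_SVM,
                target_n=2, n_repeats=2, seed=42,
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_oversized_target_fails(self, planted_small, planted_small_masks, toy_parcellation):
        from sdconnectome import anatomical_feature_specs

        _, _, _, adjs, groups = planted_small
        spec = anatomical_feature_specs(toy_parcellation)[0]
        with pytest.raises(ValueError, match="target_n"):
            subsample_connections_experiment(
                spec, planted_small_masks, adjs, groups, FAST_SVM,
                target_n=10_000, n_repeats=1, seed=0,
            )


class TestCompareSubregionDegrees:
    def _degrees(self, rows):
        return [
            DegreeVector(f"s{k}", np.asarray(r, float), None)
            for k, r in enumerate(rows)
        ]

    def test_identical_groups_all_ns(self, toy_parcellation):
        rows = [[1.0] * 12] * 6
        degs = []
        for k, r in enumerate(rows):
            degs.append(DegreeVector(f"s{k}", np.asarray(r), toy_parcellation.subregion_labels))
        table = compare_subregion_degrees(degs, ["SD"] * 3 + ["HC"] * 3, toy_parcellation, "R1")
        assert (table["direction"] == "ns").all()

    def test_hand_built_direction_and_p(self, toy_parcellation):
        # subregion 0: SD degrees (1,1,1) vs HC (2, 2.1, 1.9)
        sd_rows = [[1.0] + [5.0] * 11] * 3
        hc_rows = [[2.0] + [5.0] * 11, [2.1] + [5.0] * 11, [1.9] + [5.0] * 11]
        degs = [
            DegreeVector(f"s{k}", np.asarray(r), toy_parcellation.subregion_labels)
            for k, r in enumerate(sd_rows + hc_rows)
        ]
        table = compare_subregion_degrees(
            degs, ["SD"] * 3 + ["HC"] * 3, toy_parcellation, "R1", alpha=0.01
        ).set_index("subregion")
        first = toy_parcellation.subregion_labels[0]
        # pooled-t closed form: sp^2 = (0 + 2*0.01)/4, t = -1/sqrt(sp2*2/3)
        sp2 = (2 * 0.01) / 4
        t_oracle = -1.0 / np.sqrt(sp2 * (2 / 3))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 4)
        row = table.loc[first]
        assert row["t"] == pytest.approx(t_oracle)
        assert row["p_value"] == pytest.approx(p_oracle)
        assert row["direction"] == "SD<HC"

    def test_planted_region_subregions_lose_degree(self, planted_small, toy_parcellation):
        from sdconnectome import node_degree

        _, _, _, adjs, groups = planted_small
        degs = [node_degree(a) for a in adjs]
        table = compare_subregion_degrees(degs, groups, toy_parcellation, "R1", alpha=0.01)
        assert (table["direction"] == "SD<HC").mean() >= 0.75

    def test_weakened_subregion_flagged_across_seeds(self):
        # simulation oracle: the planted region's subregions should be flagged
        # SD<HC in nearly every replicate
        from sdconnectome import (
            CohortSpec,
            build_networks,
            generate_cohort,
            node_degree,
        )
        from sdconnectome.cohort import cohort_parcellation

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = CohortSpec(n_sd=20, n_hc=20, n_nodes=16, n_timepoints=150,
                              planted_regions=("R1",), effect_size=0.4, seed=300 + seed)
            records, series = generate_cohort(spec)
            parc = cohort_parcellation(spec)
            adjs = build_networks(series)
            degs = [node_degree(a) for a in adjs]
            table = compare_subregion_degrees(
                degs, [r.group for r in records], parc, "R1", alpha=0.01
            )
            hits += (table["direction"] == "SD<HC").all()
        assert hits >= 0.9 * n_seeds
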