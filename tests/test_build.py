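import math

import numpy as np
import pytest

from riskroc.build import (
    MISSING,
    GenotypeDataset,
    RiskNode,
    apply_model,
    cross_validated_auc,
    empirical_lr,
    fit_froc,
    forward_step,
    handle_missing,
    merge_groups,
    partition_auc,
    split_group,
)
from riskroc.core import empirical_auc
from riskroc.simulate import SimConfig, simulate_case_control

from conftest import pairwise_auc_oracle


def make_dataset(phenotype, genotypes, snp_ids=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    snp_ids = snp_ids or [f"s{j + 1}" for j in range(genotypes.shape[1])]
    ids = [f"i{k}" for k in range(len(phenotype))]
    return GenotypeDataset(ids, np.asarray(phenotype, dtype=np.int8), snp_ids, genotypes)


def root_node(data):
    idx = np.arange(data.n_samples, dtype=np.int64)
    n_case = data.n_cases
    return RiskNode(
        path={},
        n_case=n_case,
        n_control=data.n_samples - n_case,
        lr=1.0,
        indices=idx,
    )


class TestHandleMissing:
    def test_no_missing_is_identity(self):
        d = make_dataset([0, 1], [[0, 1], [2, 0]])
        out = handle_missing(d, "impute_mode")
        assert np.array_equal(out.genotypes, d.genotypes)

    def test_impute_mode_fills_with_column_mode(self):
        d = make_dataset([0, 0, 1, 1], [[0], [0], [1], [MISSING]])
        out = handle_missing(d, "impute_mode")
        assert out.genotypes[3, 0] == 0

    def test_impute_tie_goes_to_lower_code(self):
        d = make_dataset([0, 0, 1, 1], [[2], [1], [1], [2]])
        d2 = make_dataset([0, 0, 1, 1, 0], [[2], [1], [1], [2], [MISSING]])
        out = handle_missing(d2, "impute_mode")
        assert out.genotypes[4, 0] == 1

    def test_own_category_preserves_missing(self):
        d = make_dataset([0, 1], [[MISSING, 1], [2, 0]])
        out = handle_missing(d, "own_category")
        assert out.genotypes[0, 0] == MISSING

    def test_entirely_missing_snp_rejected(self):
        d = make_dataset([0, 1], [[MISSING, 1], [MISSING, 0]])
        with pytest.raises(ValueError, match="'s1'"):
            handle_missing(d, "impute_mode")

    def test_own_category_yields_extra_split_group(self):
        d = make_dataset([0, 1, 1], [[0], [1], [MISSING]])
        children = split_group(root_node(d), "s1", d)
        assert len(children) == 3
        cats = {next(iter(c.path["s1"])) for c in children}
        assert cats == {0, 1, MISSING}


class TestEmpiricalLr:
    def test_proportional_group(self):
        assert empirical_lr(5, 10, 50, 100) == pytest.approx(1.0)

    def test_direct_ratio(self):
        assert empirical_lr(10, 5, 100, 100) == pytest.approx(2.0)

    def test_zero_control_infinite(self):
        assert empirical_lr(3, 0, 100, 100) == math.inf

    def test_smoothing_keeps_order(self):
        no_controls = empirical_lr(3, 0, 100, 100, smoothing=0.5, n_groups=4)
        one_control = empirical_lr(3, 1, 100, 100, smoothing=0.5, n_groups=4)
        assert math.isfinite(no_controls)
        assert no_controls > one_control

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_lr(0, 0, 100, 100)

    def test_counts_exceed_totals(self):
        with pytest.raises(ValueError, match="exceed"):
            empirical_lr(101, 0, 100, 100)


class TestSplitGroup:
    def test_constant_column_single_child(self):
        d = make_dataset([0, 1, 1], [[0], [0], [0]])
        children = split_group(root_node(d), "s1", d)
        assert len(children) == 1
        assert children[0].n_case == 2
        assert children[0].n_control == 1

    def test_three_way_split_lrs(self):
        pheno = [1] * 10 + [0] * 10
        geno = [[g] for g in [0] * 6 + [1] * 3 + [2] * 1 + [0] * 1 + [1] * 3 + [2] * 6]
        d = make_dataset(pheno, geno)
        children = split_group(root_node(d), "s1", d)
        lr_by_cat = {next(iter(c.path["s1"])): c.lr for c in children}
        assert lr_by_cat[0] == pytest.approx(6.0)
        assert lr_by_cat[1] == pytest.approx(1.0)
        assert lr_by_cat[2] == pytest.approx(1 / 6)

    def test_count_conservation(self, rng):
        for _ in range(10):
            pheno = rng.integers(0, 2, 50)
            pheno[:2] = [0, 1]
            geno = rng.integers(0, 3, (50, 3))
            d = make_dataset(pheno, geno)
            node = root_node(d)
            children = split_group(node, "s2", d)
            assert sum(c.n_case for c in children) == node.n_case
            assert sum(c.n_control for c in children) == node.n_control

    def test_repeated_snp_rejected(self):
        d = make_dataset([0, 1], [[0, 1], [1, 0]])
        node = root_node(d)
        node.path = {"s1": frozenset([0])}
        with pytest.raises(ValueError, match="already"):
            split_group(node, "s1", d)


def leaf(n_case, n_control, lr=None, path=None):
    if lr is None:
        lr = n_case / n_control if n_control else math.inf
    return RiskNode(
        path=path or {}, n_case=n_case, n_control=n_control, lr=lr,
        indices=np.empty(0, dtype=np.int64),
    )


class TestMergeGroups:
    def test_identical_composition_always_merged(self):
        out = merge_groups([leaf(10, 10, 1.0), leaf(5, 5, 1.0)], alpha_merge=0.05)
        assert len(out) == 1
        assert out[0].n_case == 15

    def test_clearly_different_groups_kept(self):
        out = merge_groups([leaf(90, 10, 9.0), leaf(10, 90, 1 / 9)], alpha_merge=0.05)
        assert len(out) == 2

    def test_alpha_zero_disables_merging(self):
        out = merge_groups([leaf(10, 10, 1.0), leaf(5, 5, 1.0)], alpha_merge=0.0)
        assert len(out) == 2

    def test_merged_path_unions_categories(self):
        a = leaf(10, 10, 1.0, path={"s1": frozenset([0])})
        b = leaf(5, 5, 1.0, path={"s1": frozenset([2])})
        out = merge_groups([a, b], alpha_merge=0.05)
        assert out[0].path["s1"] == frozenset([0, 2])


class TestPartitionAuc:
    def test_single_leaf(self):
        assert partition_auc([leaf(10, 10, 1.0)], 10, 10) == pytest.approx(0.5)

    def test_perfect_partition(self):
        leaves = [leaf(10, 0), leaf(0, 10)]
        assert partition_auc(leaves, 10, 10) == pytest.approx(1.0)

    def test_matches_mann_whitney_on_lr_scores(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 20, size=(3, 2))
            n_case, n_control = counts[:, 0].sum(), counts[:, 1].sum()
            leaves = [
                leaf(int(c), int(k), (c / n_case) / (k / n_control) if k else math.inf)
                for c, k in counts
            ]
            expected = empirical_auc(
                np.repeat([lf.lr for lf in leaves], [lf.n_case for lf in leaves]),
                np.repeat([lf.lr for lf in leaves], [lf.n_control for lf in leaves]),
            )
            assert partition_auc(leaves, n_case, n_control) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_leaf_order(self, rng):
        counts = [(5, 2), (3, 9), (4, 4)]
        leaves = [leaf(c, k, (c / 12) / (k / 15)) for c, k in counts]
        a = partition_auc(leaves, 12, 15)
        b = partition_auc(leaves[::-1], 12, 15)
        assert a == pytest.approx(b, abs=1e-12)


class TestForwardStep:
    def _dataset(self, rng, n=60, n_snps=3):
        pheno = np.array([1] * (n // 2) + [0] * (n // 2))
        geno = rng.integers(0, 3, (n, n_snps))
        return make_dataset(pheno, geno)

    def test_single_candidate_returned(self, rng):
        d = self._dataset(rng)
        snp, _, _ = forward_step([root_node(d)], ["s2"], d)
        assert snp == "s2"

    def test_separating_snp_beats_null(self):
        pheno = [1] * 10 + [0] * 10
        geno = np.zeros((20, 2), dtype=np.int8)
        geno[:10, 1] = 2  # s2 separates perfectly
        d = make_dataset(pheno, geno)
        snp, leaves, auc = forward_step([root_node(d)], ["s1", "s2"], d)
        assert snp == "s2"
        assert auc == pytest.approx(1.0)

    def test_matches_exhaustive_candidate_oracle(self, rng):
        d = self._dataset(rng, n=100, n_snps=3)
        best = None
        for j, snp in enumerate(d.snp_ids):
            children = split_group(root_node(d), snp, d)
            merged = merge_groups(children, 0.05)
            auc = partition_auc(merged, d.n_cases, d.n_controls)
            if best is None or auc > best[0] + 1e-15:
                best = (auc, snp)
        snp, _, auc = forward_step([root_node(d)], list(d.snp_ids), d)
        assert (auc, snp) == (pytest.approx(best[0]), best[1])


def informative_config(seed, n=2000, n_null=4):
    return SimConfig(
        n_case=n,
        n_control=n,
        mafs=(0.3,) * (1 + n_null),
        rr=((1.0, 2.0, 4.0),) + ((1.0, 1.0, 1.0),) * n_null,
        prevalence=0.01,
        seed=seed,
    )


class TestFitFroc:
    def test_informative_snp_selected_first(self):
        data = simulate_case_control(informative_config(seed=11, n=1500))
        fit = fit_froc(data, max_predictors=3, k_folds=5, seed=1, stop_rule="cv")
        assert fit.selected_snps[0] == "snp1"

    def test_max_predictors_one(self):
        data = simulate_case_control(informative_config(seed=5, n=500))
        fit = fit_froc(data, max_predictors=1, k_folds=3, seed=0)
        assert len(fit.selected_snps) == 1
        assert len(fit.train_auc_per_step) == 1

    def test_train_auc_non_decreasing(self):
        cfg = SimConfig(
            n_case=800, n_control=800,
            mafs=(0.3, 0.25, 0.2),
            rr=((1, 1.5, 2.5), (1, 1.4, 2.0), (1, 1.3, 1.7)),
            prevalence=0.01, seed=21,
        )
        data = simulate_case_control(cfg)
        fit = fit_froc(data, max_predictors=3, k_folds=4, seed=2, stop_rule="fixed")
        steps = fit.train_auc_per_step
        assert all(b >= a - 1e-12 for a, b in zip(steps, steps[1:]))

    def test_kfold_out_of_range(self):
        data = simulate_case_control(informative_config(seed=1, n=50))
        with pytest.raises(ValueError, match="k_folds"):
            fit_froc(data, max_predictors=1, k_folds=1)
        with pytest.raises(ValueError, match="k_folds"):
            fit_froc(data, max_predictors=1, k_folds=51)

    def test_leaf_partition_counts(self):
        data = simulate_case_control(informative_config(seed=9, n=400))
        fit = fit_froc(data, max_predictors=2, k_folds=4, seed=3, stop_rule="fixed")
        assert sum(n.n_case for n in fit.leaf_nodes) == data.n_cases
        assert sum(n.n_control for n in fit.leaf_nodes) == data.n_controls
        covered = np.sort(np.concatenate([n.indices for n in fit.leaf_nodes]))
        assert np.array_equal(covered, np.arange(data.n_samples))

    def test_alpha_zero_step1_group_count(self):
        data = simulate_case_control(informative_config(seed=13, n=800, n_null=0))
        fit = fit_froc(data, max_predictors=1, k_folds=4, seed=0, alpha_merge=0.0)
        observed_cats = len(np.unique(data.genotypes[:, 0]))
        assert len(fit.leaf_nodes) == observed_cats

    def test_tree_parent_counts_with_alpha_zero(self):
        data = simulate_case_control(informative_config(seed=17, n=600, n_null=1))
        fit = fit_froc(
            data, max_predictors=2, k_folds=4, seed=0, alpha_merge=0.0, stop_rule="fixed"
        )

        def check(node):
            if node.children:
                assert sum(c.n_case for c in node.children) == node.n_case
                assert sum(c.n_control for c in node.children) == node.n_control
                for c in node.children:
                    check(c)

        check(fit.tree)


class TestCrossValidation:
    def test_determinism(self):
        data = simulate_case_control(informative_config(seed=3, n=400))
        a = cross_validated_auc(data, max_predictors=2, k=4, seed=7)
        b = cross_validated_auc(data, max_predictors=2, k=4, seed=7)
        assert a == b

    def test_null_snps_near_chance(self):
        cfg = SimConfig(
            n_case=1000, n_control=1000,
            mafs=(0.3, 0.2, 0.25),
            rr=((1, 1, 1),) * 3,
            prevalence=0.01, seed=31,
        )
        data = simulate_case_control(cfg)
        auc = cross_validated_auc(data, max_predictors=3, k=5, seed=1)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_cv_not_optimistic_on_average(self):
        gaps = []
        for seed in range(20):
            data = simulate_case_control(informative_config(seed=seed, n=150, n_null=2))
            fit = fit_froc(data, max_predictors=2, k_folds=5, seed=seed, stop_rule="fixed")
            gaps.append(fit.train_auc - fit.cv_auc_per_step[-1])
        assert np.mean(gaps) >= 0.0


class TestApplyModel:
    def test_self_application_reproduces_training_auc(self):
        data = simulate_case_control(informative_config(seed=23, n=500))
        fit = fit_froc(data, max_predictors=2, k_folds=4, seed=1, stop_rule="fixed")
        _, auc = apply_model(fit, data)
        assert auc == pytest.approx(fit.train_auc, abs=1e-12)

    def test_unseen_paths_score_chance(self):
        pheno = [1] * 5 + [0] * 5
        geno = np.array([[0]] * 5 + [[2]] * 5, dtype=np.int8)
        d = make_dataset(pheno, geno)
        fit = fit_froc(d, max_predictors=1, k_folds=2, seed=0, alpha_merge=0.0)
        newgeno = np.full((6, 1), 1, dtype=np.int8)  # category never seen
        new = make_dataset([1, 1, 1, 0, 0, 0], newgeno)
        scores, auc = apply_model(fit, new)
        assert np.all(scores == 1.0)
        assert auc == pytest.approx(0.5)

    def test_missing_selected_snp_rejected(self):
        data = simulate_case_control(informative_config(seed=29, n=300))
        fit = fit_froc(data, max_predictors=1, k_folds=3, seed=0)
        other = make_dataset([0, 1], [[0], [1]], snp_ids=["unrelated"])
        with pytest.raises(KeyError, match=fit.selected_snps[0]):
            apply_model(fit, other)
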