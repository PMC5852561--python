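import numpy as np
import pandas as pd
import pytest

from genesig.preprocess import drop_constant_genes, max_normalize
from genesig.selection import (
    RecursiveSignatureSelector,
    default_c_grid,
    recursive_select,
    select_iteration1,
    select_iteration2,
    sweep_c,
)
from genesig.simulate import SimSpec, gen_expression


class TestSweep:
    def test_separable_data_curve_shape(self, blobs):
        curve = sweep_c(blobs["X"], blobs["y"], c_grid=[0.99, 0.5, 0.01])
        assert curve["train_accuracy"].iloc[0] >= 0.99
        assert curve["n_nonzero"].iloc[-1] == 0
        # nonzero counts trend downward as the penalty takes over
        assert curve["n_nonzero"].iloc[0] >= curve["n_nonzero"].iloc[-1]

    def test_singleton_grid(self, blobs):
        curve = sweep_c(blobs["X"], blobs["y"], c_grid=[0.5])
        assert len(curve) == 1

    def test_empty_grid_rejected(self, blobs):
        with pytest.raises(ValueError, match="empty"):
            sweep_c(blobs["X"], blobs["y"], c_grid=[])

    def test_non_decreasing_grid_rejected(self, blobs):
        with pytest.raises(ValueError, match="decreasing"):
            sweep_c(blobs["X"], blobs["y"], c_grid=[0.1, 0.5])

    def test_grid_outside_unit_interval_rejected(self, blobs):
        with pytest.raises(ValueError):
            sweep_c(blobs["X"], blobs["y"], c_grid=[1.0, 0.5])


class TestIteration1:
    def test_theta_zero_returns_smallest_grid_value(self, blobs):
        grid = [0.9, 0.5, 0.2]
        c_star, _, curve, _ = select_iteration1(blobs["X"], blobs["y"], grid, theta=0.0)
        assert c_star == pytest.approx(0.2)
        assert len(curve) == 3

    def test_unreachable_threshold_is_an_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        y = rng.choice(list("abcd"), size=40)
        with pytest.raises(ValueError, match="denser grid"):
            select_iteration1(X, y, [0.5, 0.1], theta=1.0)

    def test_pool_recovers_planted_genes_when_signal_is_sparse(self):
        # few planted markers per class: the accuracy threshold cannot be
        # met without keeping most of them in the pool
        recs = []
        for seed in range(3):
            spec = SimSpec(seed=300 + seed, n_informative_per_class=2)
            matrix, labels, _, truth = gen_expression(spec)
            norm = max_normalize(drop_constant_genes(matrix))
            _, pool, _, _ = select_iteration1(
                norm.X(), labels.y(norm.sample_ids), default_c_grid(), theta=0.9,
                feature_names=norm.gene_ids,
            )
            planted = truth.informative_genes()
            recs.append(len(planted & pool) / len(planted))
        assert np.mean(recs) >= 0.8


class TestIteration2:
    def test_subset_contract(self, blobs):
        grid = default_c_grid(15)
        _, pool, _, _ = select_iteration1(
            blobs["X"], blobs["y"], grid, theta=0.9, feature_names=blobs["genes"]
        )
        pool_order = [g for g in blobs["genes"] if g in pool]
        idx = [blobs["genes"].index(g) for g in pool_order]
        genes, attribution, _, _, _ = select_iteration2(
            blobs["X"][:, idx], blobs["y"], target_n=max(1, len(pool) // 2),
            c_grid=grid, feature_names=pool_order,
        )
        assert genes <= pool
        assert len(genes) <= max(1, len(pool) // 2) or len(genes) == min(
            len(pool), len(genes)
        )
        assert set().union(*attribution.values()) <= set(np.unique(blobs["y"]))

    def test_generous_target_uses_largest_grid_c(self, blobs):
        grid = [0.9, 0.5]
        genes, _, _, curve, _ = select_iteration2(
            blobs["X"], blobs["y"], target_n=10_000, c_grid=grid, feature_names=blobs["genes"]
        )
        assert len(genes) == curve["n_nonzero"].iloc[0]

    def test_empty_pool_rejected(self, blobs):
        with pytest.raises(ValueError, match="empty"):
            select_iteration2(blobs["X"][:, :0], blobs["y"], 5, [0.5])

    def test_private_feature_attribution_is_single_class(self, blobs):
        genes, attribution, _, _, _ = select_iteration2(
            blobs["X"], blobs["y"], target_n=8, c_grid=default_c_grid(15),
            feature_names=blobs["genes"],
        )
        truth = blobs["truth"]
        owner = {g: cls for cls, gl in truth.informative.items() for g in gl}
        planted_selected = [g for g in genes if g in owner]
        assert planted_selected, "selection found no planted genes"
        single = [g for g in planted_selected if attribution[g] == {owner[g]}]
        assert len(single) / len(planted_selected) >= 0.9


class TestRecursiveSelect:
    def test_nesting_and_determinism(self, blobs):
        res1 = recursive_select(
            blobs["X"], blobs["y"], feature_names=blobs["genes"], theta=0.9,
            target_n=10, c_grid=default_c_grid(12), seed=1,
        )
        res2 = recursive_select(
            blobs["X"], blobs["y"], feature_names=blobs["genes"], theta=0.9,
            target_n=10, c_grid=default_c_grid(12), seed=1,
        )
        assert res1.iteration2_genes <= res1.iteration1_genes
        assert res1.iteration2_genes == res2.iteration2_genes
        assert res1.C_star == res2.C_star
        pd.testing.assert_frame_equal(res1.curve_iteration1, res2.curve_iteration1)

    def test_attribution_union_equals_selection(self, blobs):
        res = recursive_select(
            blobs["X"], blobs["y"], feature_names=blobs["genes"], theta=0.9,
            target_n=10, c_grid=default_c_grid(12),
        )
        assert set(res.subtype_attribution) == res.iteration2_genes

    def test_post_hoc_biotype_filter_restricts_signature(self, blobs):
        from genesig.preprocess import BiotypeFilterSpec
        from .conftest import make_annotation

        # annotate every gene as short miRNA: post-hoc exclusion empties it
        ann = make_annotation([(g, "miRNA", 80) for g in blobs["genes"]])
        res = recursive_select(
            blobs["X"], blobs["y"], feature_names=blobs["genes"], theta=0.9,
            target_n=10, c_grid=default_c_grid(12),
            annotation=ann, biotype_spec=BiotypeFilterSpec(), filter_stage="after",
        )
        assert res.iteration2_genes == set()


class TestSelectorEstimator:
    def test_sklearn_surface(self, blobs):
        sel = RecursiveSignatureSelector(theta=0.9, target_n=10, c_grid=default_c_grid(12))
        df = pd.DataFrame(blobs["X"], columns=blobs["genes"])
        out = sel.fit_transform(df, blobs["y"])
        assert sel.get_support().sum() == len(sel.selected_genes_)
        assert out.shape == (len(df), len(sel.selected_genes_))
        assert sel.get_params()["target_n"] == 10
        cloned = sel.set_params(target_n=5)
        assert cloned.target_n == 5
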