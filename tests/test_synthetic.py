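"""The community simulator: seeding, sparsity, markers, keystones, pairs."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict

import microformer as mf
from microformer.synthetic_data import SimConfigError, background_genera


class TestSimulateCorpus:
    def test_rows_sum_to_one(self):
        table, _ = mf.simulate_corpus(mf.SimConfig(n_samples=50, seed=0))
        np.testing.assert_allclose(table.values.sum(1), 1.0, atol=1e-9)
        assert table.values.min() >= 0

    def test_same_seed_bit_identical(self):
        cfg = mf.SimConfig(n_samples=40, seed=7)
        t1, l1 = mf.simulate_corpus(cfg)
        t2, l2 = mf.simulate_corpus(cfg)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert l1 == l2

    def test_sparsity_matches_configuration(self):
        cfg = mf.SimConfig(n_samples=500, n_genera=100, sparsity=0.8, seed=1)
        table, _ = mf.simulate_corpus(cfg)
        realized = float((table.values == 0).mean())
        assert realized == pytest.approx(cfg.sparsity, abs=0.05)

    def test_class_balance_near_uniform(self):
        cfg = mf.SimConfig(n_samples=500, n_classes=2, seed=2)
        _, labels = mf.simulate_corpus(cfg)
        frac = np.mean([l == "class0" for l in labels.values()])
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_marker_presence_enrichment_matches_effect(self):
        cfg = mf.SimConfig(n_samples=2000, n_genera=100, n_classes=2,
                           markers_per_class=5, marker_effect=5.0,
                           keystone_genera=0, keystone_coupling=0.0,
                           sparsity=0.8, seed=3)
        table, labels = mf.simulate_corpus(cfg)
        markers = mf.marker_genera(cfg)
        y = np.array([labels[s] for s in table.sample_ids])
        ratios = []
        for cls, genera in markers.items():
            own = table.values[y == cls][:, [table.genus_names.index(g)
                                             for g in genera]] > 0
            other = table.values[y != cls][:, [table.genus_names.index(g)
                                               for g in genera]] > 0
            ratios.append(own.mean() / other.mean())
        assert np.mean(ratios) == pytest.approx(cfg.marker_effect, rel=0.1)

    def test_coupled_taxa_present_only_with_keystone(self):
        cfg = mf.SimConfig(n_samples=300, n_genera=60, keystone_genera=1,
                           keystone_coupling=0.3, seed=4)
        table, _ = mf.simulate_corpus(cfg)
        k = table.genus_names.index(mf.keystone_genera(cfg)[0])
        coupled = [table.genus_names.index(g) for g in mf.coupled_genera(cfg)]
        absent_keystone = table.values[:, k] == 0
        assert (table.values[np.ix_(absent_keystone, coupled)] == 0).all()

    def test_null_configuration_is_unclassifiable(self):
        cfg = mf.SimConfig(n_samples=400, n_genera=60, n_classes=2,
                           markers_per_class=5, marker_effect=1.0,
                           keystone_genera=0, keystone_coupling=0.0, seed=5)
        table, labels = mf.simulate_corpus(cfg)
        y = np.array([labels[s] == "class1" for s in table.sample_ids], int)
        rf = RandomForestClassifier(n_estimators=100, random_state=0, n_jobs=1)
        proba = cross_val_predict(rf, table.values, y, cv=3,
                                  method="predict_proba")[:, 1]
        assert roc_auc_score(y, proba) == pytest.approx(0.5, abs=0.1)

    def test_min_present_floor_enforced(self):
        cfg = mf.SimConfig(n_samples=100, n_genera=60, sparsity=0.8,
                           min_present=10, seed=6)
        table, _ = mf.simulate_corpus(cfg)
        assert ((table.values > 0).sum(1) >= 10).all()

    @pytest.mark.parametrize("kwargs", [
        dict(sparsity=0.0), dict(sparsity=1.0), dict(marker_effect=0.5),
        dict(n_genera=8, markers_per_class=5, n_classes=2),
        dict(sparsity=0.95, n_genera=60, min_present=10),
        dict(geometric_rate=1.5),
    ])
    def test_infeasible_configurations_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            mf.SimConfig(**kwargs)

    def test_planted_block_partition_is_consistent(self):
        cfg = mf.SimConfig(n_genera=100, seed=0)
        names = (mf.keystone_genera(cfg) + mf.coupled_genera(cfg)
                 + [g for gs in mf.marker_genera(cfg).values() for g in gs]
                 + background_genera(cfg))
        assert sorted(names) == sorted({f"g{j:03d}" for j in range(100)})


class TestRankAbundancePairs:
    def test_geometric_closed_form_three_taxa(self):
        # rate 0.5 over 3 taxa: abundances 4/7, 2/7, 1/7
        cfg = mf.SimConfig(n_genera=3, sparsity=0.01, geometric_rate=0.5,
                           abundance_law="geometric_decay",
                           markers_per_class=0, keystone_genera=0,
                           keystone_coupling=0.0, seed=0)
        pairs = mf.simulate_rank_abundance_pairs(cfg, 5)
        for p in pairs:
            if len(p.genus_indices) == 3:
                ordered = p.abundances[list(p.genus_indices)]
                np.testing.assert_allclose(ordered, [4 / 7, 2 / 7, 1 / 7],
                                           atol=1e-12)

    def test_pairs_are_self_consistent(self):
        cfg = mf.SimConfig(n_genera=40, sparsity=0.85,
                           abundance_law="geometric_decay", seed=8)
        for p in mf.simulate_rank_abundance_pairs(cfg, 50):
            m = len(p.genus_indices)
            rerank = tuple(int(j) for j in np.argsort(-p.abundances)[:m])
            assert rerank == p.genus_indices
            assert p.abundances.sum() == pytest.approx(1.0)
            # the stated law holds exactly: ratios of successive ranks
            ordered = p.abundances[list(p.genus_indices)]
            np.testing.assert_allclose(ordered[1:] / ordered[:-1],
                                       cfg.geometric_rate, atol=1e-9)

    def test_pairs_deterministic_by_seed(self):
        cfg = mf.SimConfig(n_genera=20, sparsity=0.7, seed=9,
                           abundance_law="geometric_decay")
        a = mf.simulate_rank_abundance_pairs(cfg, 10)
        b = mf.simulate_rank_abundance_pairs(cfg, 10)
        for pa, pb in zip(a, b):
            assert pa.genus_indices == pb.genus_indices
            np.testing.assert_array_equal(pa.abundances, pb.abundances)

    def test_dirichlet_law_also_self_consistent(self):
        cfg = mf.SimConfig(n_genera=20, sparsity=0.7, seed=10,
                           abundance_law="dirichlet")
        for p in mf.simulate_rank_abundance_pairs(cfg, 20):
            m = len(p.genus_indices)
            rerank = tuple(int(j) for j in np.argsort(-p.abundances)[:m])
            assert rerank == p.genus_indices
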