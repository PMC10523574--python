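"""Synthetic multi-partner world generator."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from fluidsim.chem_features import featurize, standardize_records
from fluidsim.evaluation import class_ratio
from fluidsim.synthetic_data import (
    WorldConfig,
    generate_world,
    label_activity,
    temporal_split,
)
from fluidsim.chem_features import MoleculeRecord


class TestLabelActivity:
    @pytest.mark.parametrize(
        "response, expected",
        [(50.0, 1), (49.99, 0), (-5.0, 0), (100.0, 1), (0.0, 0)],
    )
    def test_threshold_boundary(self, response, expected):
        # the boundary value itself counts as active (>=, not >)
        assert label_activity(response) == expected

    def test_vectorized_and_custom_threshold(self):
        out = label_activity(np.array([10.0, 70.0, 70.0]), threshold=70.0)
        assert out.tolist() == [0, 1, 1]


class TestTemporalSplit:
    def test_partition_at_cutoff(self):
        recs = [
            MoleculeRecord(f"m{y}", "C", 1, y, "P", "T")
            for y in (2018, 2019, 2020, 2021)
        ]
        train, test, warn = temporal_split(recs, 2020)
        assert len(train) == 2 and len(test) == 2 and not warn
        assert all(r.assay_year < 2020 for r in train)
        assert all(r.assay_year >= 2020 for r in test)

    def test_degenerate_side_warns_not_fails(self):
        recs = [MoleculeRecord("m", "C", 1, 2021, "P", "T")]
        train, test, warn = temporal_split(recs, 2020)
        assert train == [] and len(test) == 1
        assert any("empty training side" in w for w in warn)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        recs = [
            MoleculeRecord(f"m{i}", "C", 0, int(y), "P", "T")
            for i, y in enumerate(rng.integers(2010, 2025, size=200))
        ]
        train, test, _ = temporal_split(recs)
        assert len(train) + len(test) == len(recs)
        assert {r.id for r in train} | {r.id for r in test} == {r.id for r in recs}


class TestWorldGeneration:
    def test_same_config_same_seed_identical_worlds(self):
        kwargs = dict(n_train_per_partner=200, n_test_per_partner=80,
                      n_public=200, n_pool=500, seed=5)
        w1 = generate_world(WorldConfig(**kwargs))
        w2 = generate_world(WorldConfig(**kwargs))
        assert [r.id for r in w1.pool.records] == [r.id for r in w2.pool.records]
        assert np.array_equal(w1.pool.features.physchem, w2.pool.features.physchem)
        assert np.array_equal(
            w1.partner_train["P0"].features.fingerprints,
            w2.partner_train["P0"].features.fingerprints,
        )
        assert np.array_equal(w1.pool_ground_truth(), w2.pool_ground_truth())

    def test_pool_labels_hidden_but_oracle_available(self, tiny_world):
        assert all(r.label is None for r in tiny_world.pool.records)
        assert np.all(tiny_world.pool.features.labels == -1)
        truth = tiny_world.pool_ground_truth()
        assert set(np.unique(truth)) <= {0, 1}
        assert len(truth) == len(tiny_world.pool)

    def test_temporal_invariant(self, tiny_world):
        cutoff = tiny_world.config.temporal_cutoff_year
        for pid in tiny_world.partner_ids:
            assert all(r.assay_year < cutoff for r in tiny_world.partner_train[pid].records)
            assert all(r.assay_year >= cutoff for r in tiny_world.partner_test[pid].records)

    def test_dataset_ids_disjoint(self, tiny_world):
        seen = set()
        for _, ds in (
            [(p, tiny_world.partner_train[p]) for p in tiny_world.partner_ids]
            + [(p, tiny_world.partner_test[p]) for p in tiny_world.partner_ids]
            + [("pub", tiny_world.public), ("pool", tiny_world.pool)]
        ):
            ids = {r.id for r in ds.records}
            assert not (ids & seen)
            seen |= ids

    def test_realized_ratio_tracks_request(self):
        # binomial bound: at n=10,000 and ratio 1.0 the realized ratio is
        # within [0.9, 1.1] with overwhelming probability
        cfg = WorldConfig(n_partners=1, n_train_per_partner=10_000,
                          n_test_per_partner=0, n_public=0, n_pool=0,
                          inactive_active_ratio=1.0, seed=3)
        w = generate_world(cfg)
        r = class_ratio(w.partner_train["P0"].labels)
        assert 0.9 <= r <= 1.1

    @pytest.mark.parametrize("seed", range(3))
    def test_per_dataset_ratio_within_tolerance(self, seed):
        cfg = WorldConfig(n_train_per_partner=5000, n_test_per_partner=0,
                          n_public=5000, n_pool=0, seed=seed)
        w = generate_world(cfg)
        req = cfg.inactive_active_ratio
        for ds in [w.partner_train[p] for p in w.partner_ids] + [w.public]:
            assert abs(class_ratio(ds.labels) - req) <= 0.1 * req

    def test_unattainable_ratio_names_dataset(self):
        cfg = WorldConfig(n_partners=1, n_train_per_partner=5,
                          n_test_per_partner=0, n_public=0, n_pool=0,
                          inactive_active_ratio=50.0, seed=0)
        with pytest.raises(ValueError, match="P0-train"):
            generate_world(cfg)

    def test_full_overlap_partners_share_cluster_mixture(self):
        # overlap=1: both partners draw from identical cluster mixtures, so
        # their latent score distributions are statistically equal
        pvals = []
        for seed in range(20):
            cfg = WorldConfig(n_partners=2, n_train_per_partner=400,
                              n_test_per_partner=0, n_public=0, n_pool=0,
                              partner_cluster_overlap=1.0, seed=seed)
            w = generate_world(cfg)
            a = w.partner_train["P0"].features.physchem[:, 0]
            b = w.partner_train["P1"].features.physchem[:, 0]
            pvals.append(ks_2samp(a, b).pvalue)
        # distributional equality: at alpha=0.01, expect ~0 rejections
        assert np.mean(np.array(pvals) < 0.01) <= 0.10

    def test_zero_overlap_partners_differ(self):
        cfg = WorldConfig(n_partners=2, n_train_per_partner=400,
                          n_test_per_partner=0, n_public=0, n_pool=0,
                          partner_cluster_overlap=0.0, test_novelty=0.0, seed=1)
        w = generate_world(cfg)
        a = w.partner_train["P0"].features.fingerprints.mean(axis=0)
        b = w.partner_train["P1"].features.fingerprints.mean(axis=0)
        # disjoint cluster bit pools -> very different bit frequencies
        assert np.abs(a - b).max() > 0.2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(partner_cluster_overlap=1.5).validate()
        with pytest.raises(ValueError):
            WorldConfig(label_noise=-0.1).validate()
        with pytest.raises(ValueError):
            WorldConfig(mode="quantum").validate()

    def test_ground_truth_recoverable_by_strong_classifier(self):
        # single-series recovery world: activity is purely logistic in the
        # latent projection, so a regularized logistic learner is exactly
        # specified and approaches the accuracy ceiling implied by the
        # gross label-error rate
        from sklearn.linear_model import LogisticRegression

        accs = []
        for seed in range(5):
            cfg = WorldConfig(n_partners=1, n_train_per_partner=5000,
                              n_test_per_partner=1500, n_public=0, n_pool=0,
                              partner_cluster_overlap=1.0, n_clusters=1,
                              label_noise=0.02, assay_noise=0.0,
                              test_novelty=0.0, seed=seed)
            w = generate_world(cfg)
            tr = w.partner_train["P0"].features
            te = w.partner_test["P0"].features
            clf = LogisticRegression(C=0.05, max_iter=2000)
            accs.append(clf.fit(tr.X, tr.labels).score(te.X, te.labels))
        assert np.mean(accs) >= 1.0 - cfg.label_noise - 0.05


class TestSmilesMode:
    def test_grammar_molecules_parse_and_featurize(self, tiny_smiles_world):
        recs = tiny_smiles_world.partner_train["P0"].records
        assert all(r.smiles for r in recs)
        std, rejected = standardize_records(recs[:40], on_error="drop")
        assert not rejected
        fm = featurize(std)
        assert fm.physchem.shape[0] == 40

    def test_smiles_mode_has_no_precomputed_features(self, tiny_smiles_world):
        assert tiny_smiles_world.partner_train["P0"].features is None
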