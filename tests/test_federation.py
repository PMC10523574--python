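"""Pool prediction, consolidation, and federated-set construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fluidsim.federation import (
    FederatedSet,
    build_federated_set,
    consolidate,
    federated_feature_matrix,
    predict_pool,
)
from fluidsim.teacher_models import train_teacher


def member_frame(ids, labels, decidabilities, reliabilities, member="A"):
    labels = np.asarray(labels)
    dec = np.asarray(decidabilities, dtype=float)
    proba = np.where(labels == 1, (1 + dec) / 2, (1 - dec) / 2)
    return pd.DataFrame({
        "molecule_id": ids, "member_id": member, "predicted_label": labels,
        "probability": proba, "decidability": dec,
        "reliability": np.asarray(reliabilities, dtype=float),
    })


def brute_force_selector(consolidated, n_per_class, reliability_min):
    """Independent reference: filter, per-class sort, slice, cross-fill."""
    elig = consolidated[consolidated["consensus_reliability"] >= reliability_min]
    ranked = {
        lab: elig[elig["consensus_label"] == lab].sort_values(
            ["consensus_decidability", "consensus_reliability", "molecule_id"],
            ascending=[False, False, True],
        )["molecule_id"].tolist()
        for lab in (1, 0)
    }
    n1 = min(n_per_class, len(ranked[1]))
    n0 = min(n_per_class, len(ranked[0]))
    short1, short0 = n_per_class - n1, n_per_class - n0
    n0 = min(n0 + short1, len(ranked[0]))
    n1 = min(n1 + short0, len(ranked[1]))
    return set(ranked[1][:n1]), set(ranked[0][:n0])


class TestPredictPool:
    def test_record_bookkeeping(self, tiny_world):
        teacher = train_teacher(tiny_world.partner_train["P0"].features,
                                architecture="sgd", seed=0)
        pool = tiny_world.pool.features
        pred = predict_pool(teacher, pool, member_id="P0")
        assert len(pred) == len(pool)
        assert set(pred["molecule_id"]) == set(pool.ids)
        assert pred["probability"].between(0, 1).all()
        assert np.allclose(pred["decidability"],
                           np.abs(2 * pred["probability"] - 1))

    def test_empty_pool_gives_empty_frame(self, tiny_world):
        teacher = train_teacher(tiny_world.partner_train["P0"].features,
                                architecture="gnb", seed=0)
        empty = tiny_world.pool.features.subset(np.array([], dtype=int))
        assert len(predict_pool(teacher, empty, "P0")) == 0

    def test_training_molecule_in_pool_scores_full_reliability(self, tiny_world):
        # self-similarity: at k=1 an exact training molecule scores 1.0
        train = tiny_world.partner_train["P0"].features
        teacher = train_teacher(train, architecture="gnb", seed=0)
        probe = train.subset(np.arange(4))
        pred = predict_pool(teacher, probe, "P0", reliability_k=1)
        assert np.allclose(pred["reliability"], 1.0)


class TestConsolidate:
    def test_single_member_identity(self):
        a = member_frame(["m1", "m2", "m3"], [1, 0, 1], [0.8, 0.4, 0.1], [0.5, 0.6, 0.7])
        out = consolidate([a])
        assert out["consensus_label"].tolist() == [1, 0, 1]
        assert out["consensus_decidability"].tolist() == pytest.approx([0.8, 0.4, 0.1])
        assert out["consensus_reliability"].tolist() == pytest.approx([0.5, 0.6, 0.7])
        assert out["member_agreement"].tolist() == [1.0, 1.0, 1.0]

    def test_unanimous_vote_and_mean_decidability(self):
        frames = [
            member_frame(["m"], [1], [d], [0.5], member=m)
            for m, d in zip("ABC", (0.2, 0.4, 0.6))
        ]
        out = consolidate(frames)
        assert out.loc[0, "consensus_label"] == 1
        assert out.loc[0, "consensus_decidability"] == pytest.approx(0.4)
        assert out.loc[0, "n_members"] == 3

    def test_weighted_vote_oracle_two_member_split(self):
        # label 1 voter at decidability 0.9 outweighs label 0 at 0.3;
        # oracle: enumerate both outcomes and compare weights directly
        a = member_frame(["m"], [1], [0.9], [0.5], member="A")
        b = member_frame(["m"], [0], [0.3], [0.5], member="B")
        out = consolidate([a, b])
        assert out.loc[0, "consensus_label"] == 1
        assert out.loc[0, "member_agreement"] == pytest.approx(0.5)
        # flipped weights flip the call
        a2 = member_frame(["m"], [1], [0.3], [0.5], member="A")
        b2 = member_frame(["m"], [0], [0.9], [0.5], member="B")
        assert consolidate([a2, b2]).loc[0, "consensus_label"] == 0

    def test_exact_tie_resolves_to_inactive(self):
        a = member_frame(["m"], [1], [0.5], [0.5], member="A")
        b = member_frame(["m"], [0], [0.5], [0.5], member="B")
        assert consolidate([a, b]).loc[0, "consensus_label"] == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ids = [f"m{i}" for i in range(40)]
        frames = [
            member_frame(ids, rng.integers(0, 2, 40), rng.random(40),
                         rng.random(40), member=m)
            for m in "ABC"
        ]
        base = consolidate(frames)
        for perm in itertools.permutations(frames):
            out = consolidate(list(perm))
            pd.testing.assert_frame_equal(out, base)

    def test_mismatched_id_sets_listed(self):
        a = member_frame(["m1", "m2"], [1, 0], [0.5, 0.5], [0.5, 0.5], "A")
        b = member_frame(["m1", "m3"], [1, 0], [0.5, 0.5], [0.5, 0.5], "B")
        with pytest.raises(ValueError, match="m2"):
            consolidate([a, b])

    @pytest.mark.parametrize("rule", ["majority", "mean_probability"])
    def test_alternative_rules_run(self, rule):
        frames = [
            member_frame(["m1", "m2"], [1, 0], [0.9, 0.1], [0.5, 0.5], m)
            for m in "AB"
        ]
        out = consolidate(frames, rule=rule)
        assert set(out["consensus_label"]) <= {0, 1}


def synth_consolidated(n_pos, n_neg, rng, rel_low=0.0):
    n = n_pos + n_neg
    return pd.DataFrame({
        "molecule_id": [f"m{i:05d}" for i in range(n)],
        "consensus_label": np.array([1] * n_pos + [0] * n_neg),
        "consensus_decidability": rng.random(n),
        "consensus_reliability": rel_low + (1 - rel_low) * rng.random(n),
        "n_members": 3,
        "member_agreement": 1.0,
    })


class TestBuildFederatedSet:
    def test_balanced_case_exact(self):
        rng = np.random.default_rng(0)
        fed = build_federated_set(synth_consolidated(500, 500, rng, rel_low=0.01),
                                  n_per_class=100, reliability_min=0.005)
        assert fed.n_pos == 100 and fed.n_neg == 100

    def test_cross_class_fill(self):
        rng = np.random.default_rng(1)
        fed = build_federated_set(synth_consolidated(30, 500, rng, rel_low=0.01),
                                  n_per_class=100, reliability_min=0.005)
        assert fed.n_pos == 30 and fed.n_neg == 170 and len(fed) == 200

    def test_both_classes_exhausted_warns(self):
        rng = np.random.default_rng(2)
        fed = build_federated_set(synth_consolidated(30, 40, rng, rel_low=0.01),
                                  n_per_class=100, reliability_min=0.005)
        assert len(fed) == 70
        assert any("short" in w for w in fed.warnings)

    def test_all_below_reliability_threshold_empty_with_warning(self):
        rng = np.random.default_rng(3)
        cons = synth_consolidated(50, 50, rng)
        cons["consensus_reliability"] = 0.001
        fed = build_federated_set(cons, n_per_class=10, reliability_min=0.005)
        assert len(fed) == 0 and fed.warnings

    def test_included_decidability_dominates_excluded(self):
        rng = np.random.default_rng(4)
        cons = synth_consolidated(300, 300, rng, rel_low=0.01)
        fed = build_federated_set(cons, n_per_class=50, reliability_min=0.005)
        for lab in (0, 1):
            inc = fed.records[fed.records["label"] == lab]["decidability"]
            chosen = set(fed.records["molecule_id"])
            exc = cons[(cons["consensus_label"] == lab)
                       & ~cons["molecule_id"].isin(chosen)]["consensus_decidability"]
            if len(inc) and len(exc):
                assert inc.min() >= exc.max() - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_selector(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(0, 300, size=2)
        n_per_class = int(rng.integers(1, 150))
        rmin = float(rng.random() * 0.5)
        cons = synth_consolidated(int(n_pos), int(n_neg), rng)
        fed = build_federated_set(cons, n_per_class=n_per_class, reliability_min=rmin)
        pos_ids, neg_ids = brute_force_selector(cons, n_per_class, rmin)
        assert set(fed.records[fed.records["label"] == 1]["molecule_id"]) == pos_ids
        assert set(fed.records[fed.records["label"] == 0]["molecule_id"]) == neg_ids

    def test_csv_with_provenance_sidecar(self, tmp_path):
        rng = np.random.default_rng(5)
        fed = build_federated_set(synth_consolidated(50, 50, rng, rel_low=0.01),
                                  n_per_class=10, provenance={"members": ["A"]})
        path = tmp_path / "fed.csv"
        fed.to_csv(path)
        assert path.exists() and (tmp_path / "fed.csv.provenance.json").exists()

    def test_feature_matrix_materialization(self, tiny_world):
        pool = tiny_world.pool.features
        rng = np.random.default_rng(6)
        cons = pd.DataFrame({
            "molecule_id": pool.ids,
            "consensus_label": rng.integers(0, 2, len(pool)),
            "consensus_decidability": rng.random(len(pool)),
            "consensus_reliability": 0.5,
            "n_members": 1, "member_agreement": 1.0,
        })
        fed = build_federated_set(cons, n_per_class=40, reliability_min=0.005)
        fm = federated_feature_matrix(fed, pool)
        assert fm.ids == fed.records["molecule_id"].tolist()
        assert np.array_equal(fm.labels, fed.records["label"].to_numpy())
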