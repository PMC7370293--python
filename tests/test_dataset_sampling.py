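import numpy as np
import pytest
from sklearn.neighbors import NearestNeighbors

from rccppi import (
    NEGATIVE,
    POSITIVE,
    PPIDataset,
    SamplingGridSpec,
    enumerate_test_grid,
    enumerate_training_grid,
    remove_redundancy,
    smote_oversample,
    split_by_domain,
    undersample,
)


def make_dataset(n_pos, n_neg, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.poisson(3.0, size=(n_pos + n_neg, dim)).astype(float)
    y = np.array([POSITIVE] * n_pos + [NEGATIVE] * n_neg, dtype=object)
    return PPIDataset(X, y)


class TestUndersample:
    @pytest.mark.parametrize("ratio, expect_pos", [(1, 30), (2, 60), (3, 90)])
    def test_positive_count_is_ratio_times_negatives(self, ratio, expect_pos):
        ds = make_dataset(n_pos=150, n_neg=30)
        out = undersample(ds, ratio, seed=5)
        assert out.n_positive == expect_pos
        assert out.n_negative == 30

    def test_all_negatives_kept_no_positive_duplicated(self):
        ds = make_dataset(60, 20, seed=3)
        out = undersample(ds, 2, seed=1)
        neg_rows = {tuple(r) for r in ds.features[ds.labels == NEGATIVE]}
        out_neg_rows = {tuple(r) for r in out.features[out.labels == NEGATIVE]}
        assert out_neg_rows == neg_rows
        # sampling without replacement: selected positives are a sub-multiset
        pos_in = sorted(map(tuple, ds.features[ds.labels == POSITIVE]))
        pos_out = sorted(map(tuple, out.features[out.labels == POSITIVE]))
        it = iter(pos_in)
        assert all(any(row == cand for cand in it) for row in pos_out)

    def test_deterministic_under_seed(self):
        ds = make_dataset(100, 25)
        a = undersample(ds, 1, seed=7)
        b = undersample(ds, 1, seed=7)
        np.testing.assert_array_equal(a.features, b.features)

    def test_insufficient_positives_rejected(self):
        with pytest.raises(ValueError, match="cannot satisfy ratio"):
            undersample(make_dataset(10, 20), 1, seed=0)


class TestSmote:
    def test_minority_count_multiplied(self):
        ds = make_dataset(n_pos=80, n_neg=20)
        for factor in (2, 3):
            out = smote_oversample(ds, factor, seed=2)
            assert out.n_negative == factor * 20
            assert out.n_positive == 80

    def test_contains_unmodified_original_minority(self):
        ds = make_dataset(50, 15, seed=4)
        out = smote_oversample(ds, 2, seed=9)
        orig = [tuple(r) for r in ds.features[ds.labels == NEGATIVE]]
        new = [tuple(r) for r in out.features[out.labels == NEGATIVE]]
        for row in orig:
            assert row in new

    def test_synthetics_lie_on_neighbor_segments(self):
        ds = make_dataset(60, 25, seed=1)
        k = 5
        out = smote_oversample(ds, 2, k_neighbors=k, seed=3)
        X = ds.features[ds.labels == NEGATIVE]
        synth = out.features[len(ds):]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, neigh = nn.kneighbors(X)
        for i, s in enumerate(synth):  # parent order is the minority order
            x = X[i]
            ok = False
            for j in neigh[i, 1:]:
                z, d = X[j], s - x
                seg = z - x
                denom = float(seg @ seg)
                if denom == 0:
                    ok = ok or np.allclose(s, x)
                    continue
                u = float(d @ seg) / denom
                if -1e-9 <= u < 1 + 1e-9 and np.allclose(x + u * seg, s, atol=1e-9):
                    ok = True
            assert ok, f"synthetic {i} not on any parent-neighbor segment"

    def test_duplicated_minority_reproduces_originals(self):
        X = np.vstack([np.tile([1.0, 2.0], (8, 1)), np.ones((30, 2))])
        y = np.array([NEGATIVE] * 8 + [POSITIVE] * 30, dtype=object)
        out = smote_oversample(PPIDataset(X, y), 2, k_neighbors=5, seed=0)
        synth = out.features[38:]
        np.testing.assert_allclose(synth, np.tile([1.0, 2.0], (8, 1)))

    def test_too_few_minority_rejected(self):
        with pytest.raises(ValueError, match="too few minority"):
            smote_oversample(make_dataset(20, 4), 2, k_neighbors=5)

    def test_deterministic_under_seed(self):
        ds = make_dataset(40, 12)
        a = smote_oversample(ds, 3, seed=11)
        b = smote_oversample(ds, 3, seed=11)
        np.testing.assert_array_equal(a.features, b.features)


class TestRemoveRedundancy:
    def test_disjoint_unique_sets_unchanged(self):
        train = make_dataset(5, 5, seed=0)
        test = PPIDataset(train.features + 100.0, train.labels)
        tr, te = remove_redundancy(train, test)
        assert len(tr) == 5 + 5 and len(te) == 10

    def test_train_test_overlap_dropped_from_test(self):
        X = np.arange(8.0).reshape(4, 2)
        train = PPIDataset(X, np.array([POSITIVE] * 4, dtype=object))
        test = PPIDataset(
            np.vstack([X[1], X[1] + 50]), np.array([POSITIVE] * 2, dtype=object)
        )
        tr, te = remove_redundancy(train, test)
        assert len(tr) == 4
        assert [tuple(r) for r in te.features] == [tuple(X[1] + 50)]

    def test_within_partition_duplicates_collapse_to_first(self):
        X = np.vstack([np.ones(2)] * 5 + [np.zeros(2)])
        y = np.array([POSITIVE] * 5 + [NEGATIVE], dtype=object)
        tr, te = remove_redundancy(
            PPIDataset(X, y), PPIDataset(np.full((1, 2), 9.0),
                                         np.array([NEGATIVE], dtype=object))
        )
        assert len(tr) == 2
        assert tr.labels[0] == POSITIVE  # first occurrence kept

    def test_no_shared_vectors_after_cleanup(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(40, 3)).astype(float)
        train = PPIDataset(X[:25], np.array([POSITIVE] * 25, dtype=object))
        test = PPIDataset(X[15:], np.array([NEGATIVE] * 25, dtype=object))
        tr, te = remove_redundancy(train, test)
        tr_keys = {tuple(r) for r in tr.features}
        te_keys = {tuple(r) for r in te.features}
        assert not (tr_keys & te_keys)
        assert len(tr_keys) == len(tr) and len(te_keys) == len(te)


class TestGrids:
    def test_default_spec_cardinalities(self):
        spec = SamplingGridSpec()
        train = enumerate_training_grid(spec)
        under = [c for c in train if c.branch == "undersample"]
        over = [c for c in train if c.branch == "oversample"]
        assert (len(under), len(over), len(train)) == (216, 144, 360)
        assert len(enumerate_test_grid(spec)) == 24

    def test_reduced_spec_cardinalities(self):
        spec = SamplingGridSpec(replicates=1, scalings=("raw",))
        assert len(enumerate_training_grid(spec)) == 8 * 3 + 8 * 2
        assert len(enumerate_test_grid(spec)) == 8
        single = SamplingGridSpec(
            cutoffs=(7,), atom_modes=("SC",), combine_modes=("sum",),
            scalings=("raw",), replicates=1,
        )
        assert len(enumerate_test_grid(single)) == 1

    def test_enumeration_is_pure(self):
        a = enumerate_training_grid(SamplingGridSpec(base_seed=3))
        b = enumerate_training_grid(SamplingGridSpec(base_seed=3))
        assert a == b

    def test_oversample_seed_comes_from_1to1_undersample(self):
        train = enumerate_training_grid(SamplingGridSpec())
        under_1to1 = {
            (c.cutoff, c.atom_mode, c.combine_mode, c.replicate): c.seed
            for c in train if c.branch == "undersample" and c.ratio == 1
        }
        for c in train:
            if c.branch == "oversample":
                key = (c.cutoff, c.atom_mode, c.combine_mode, c.replicate)
                assert c.seed == under_1to1[key]


class TestSplitByDomain:
    annotations = {f"p{i}": {f"D{i % 3}"} for i in range(12)}

    def test_majority_goes_to_train(self):
        pairs = [(f"p{i}", f"p{i + 1}", POSITIVE) for i in range(0, 10)]
        ann = {f"p{i}": {"D1"} for i in range(11)}
        train, test = split_by_domain(pairs, ann)
        assert len(test) <= 5 <= len(train)

    def test_singleton_domain_combination_trains_only(self):
        pairs = [("a", "b", POSITIVE)]
        train, test = split_by_domain(pairs, {"a": {"D1"}, "b": {"D2"}})
        assert train == pairs and test == []

    def test_negatives_shared_in_redundant_mode(self):
        pairs = [("a", "b", POSITIVE), ("c", "d", NEGATIVE)]
        ann = {k: {"D"} for k in "abcd"}
        train, test = split_by_domain(pairs, ann, negative_policy="shared")
        assert ("c", "d", NEGATIVE) in train and ("c", "d", NEGATIVE) in test

    def test_negatives_partitioned_in_split_mode(self):
        pairs = [(f"n{i}", f"m{i}", NEGATIVE) for i in range(10)]
        ann = {}
        train, test = split_by_domain(pairs, ann, negative_policy="split", seed=1)
        assert len(test) == 2 and len(train) == 8
        assert not (set(train) & set(test))

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError, match="missing domain annotation"):
            split_by_domain([("a", "zz", POSITIVE)], {"a": {"D"}})
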