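"""Oversampling algorithms: counts, geometry, moments, determinism."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from clinaug.augmentation import (
    NoiseSpec,
    _largest_remainder,
    adasyn,
    augment,
    gnus,
    knn_indices,
    random_upsample,
    smote,
)
from clinaug.data_model import LabeledTable

from conftest import make_table


class TestKnnIndices:
    def test_nearest_excluding_self(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        got = knn_indices(ref, ref[0], k=1, exclude_self=True, self_index=0)
        assert list(got) == [1]

    def test_k_equals_all_other_rows(self, rng):
        ref = rng.normal(size=(8, 3))
        got = knn_indices(ref, ref[2], k=7, exclude_self=True, self_index=2)
        assert sorted(got) == [0, 1, 3, 4, 5, 6, 7]

    def test_matches_bruteforce_distance_sort(self, rng):
        ref = rng.normal(size=(20, 3))
        q = rng.normal(size=3)
        got = knn_indices(ref, q, k=4)
        d = np.sqrt(((ref - q) ** 2).sum(axis=1))
        expected = sorted(range(20), key=lambda i: (d[i], i))[:4]
        assert list(got) == expected

    def test_ties_break_to_lower_index(self):
        ref = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        got = knn_indices(ref, np.zeros(2), k=2)
        assert list(got) == [0, 1]

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_indices(np.zeros((3, 2)), np.zeros(2), k=4)


class TestRandomUpsample:
    def test_balances_counts(self, small_table):
        r = random_upsample(small_table, rng_seed=0)
        assert r.n_synthetic == 6
        assert r.table.n_cases == r.table.n_controls == 10

    def test_balanced_input_unchanged(self):
        t = make_table(n_controls=5, n_cases=5)
        r = random_upsample(t, rng_seed=0)
        assert r.n_synthetic == 0
        np.testing.assert_array_equal(r.table.features, t.features)

    def test_seeded_replay_reproduces_draws(self):
        t = make_table(n_controls=100, n_cases=10, seed=3)
        r = random_upsample(t, rng_seed=77)
        oracle = np.random.default_rng(77).choice(t.case_indices, size=90, replace=True)
        np.testing.assert_array_equal(r.provenance["source"].to_numpy(), oracle)
        np.testing.assert_array_equal(r.table.features[100 + 10:], t.features[oracle])


class TestGnus:
    def test_small_scale_converges_to_upsample(self, small_table):
        up = random_upsample(small_table, rng_seed=5)
        g = gnus(small_table, NoiseSpec(scale=1e-12), rng_seed=5)
        np.testing.assert_allclose(g.table.features, up.table.features, atol=1e-9)

    def test_constant_minority_feature_gets_exact_mean_shift(self):
        x = np.random.default_rng(0).normal(size=(12, 2))
        y = np.array([0] * 9 + [1] * 3)
        c = 4.0
        x[y == 1, 0] = c  # constant minority column -> sigma = 0
        t = LabeledTable(x, y)
        g = gnus(t, rng_seed=1)
        synth = g.table.features[g.synthetic_mask]
        np.testing.assert_allclose(synth[:, 0], c + 0.001 * c, rtol=1e-12)

    def test_moment_recovery(self):
        # empirical mean/sd of (synthetic - source copy) recover the noise law
        t = make_table(n_controls=2000, n_cases=8, seed=9)
        g = gnus(t, rng_seed=4)
        x_min = t.features[t.case_indices]
        mu = 0.001 * x_min.mean(axis=0)
        sigma = 0.001 * x_min.std(axis=0, ddof=1)
        deltas = g.table.features[g.synthetic_mask] - t.features[g.provenance["source"]]
        n = len(deltas)
        se_mean = sigma / np.sqrt(n)
        assert np.all(np.abs(deltas.mean(axis=0) - mu) <= 3 * se_mean)
        se_sd = sigma / np.sqrt(2 * (n - 1))
        assert np.all(np.abs(deltas.std(axis=0, ddof=1) - sigma) <= 3 * se_sd)

    def test_singleton_minority_warns_and_duplicates(self):
        x = np.random.default_rng(2).normal(size=(6, 2))
        y = np.array([0, 0, 0, 0, 0, 1])
        t = LabeledTable(x, y)
        with pytest.warns(UserWarning, match="size 1"):
            g = gnus(t, rng_seed=0)
        synth = g.table.features[g.synthetic_mask]
        np.testing.assert_allclose(synth, np.broadcast_to(x[5] + 0.001 * x[5], synth.shape),
                                   rtol=1e-12)

    def test_zero_centered_option_removes_mean_shift(self):
        t = make_table(n_controls=500, n_cases=6, seed=1, shift=50.0)
        g = gnus(t, NoiseSpec(scale=0.01, zero_centered=True), rng_seed=2)
        deltas = g.table.features[g.synthetic_mask] - t.features[g.provenance["source"]]
        assert np.abs(deltas.mean(axis=0)).max() < 0.01  # no 0.01*50 shift


class TestSmote:
    def test_two_identical_minority_points(self):
        x = np.zeros((8, 2))
        x[:6] = np.random.default_rng(0).normal(size=(6, 2))
        x[6] = x[7] = [2.0, 3.0]
        t = LabeledTable(x, [0] * 6 + [1] * 2)
        s = smote(t, k=5, rng_seed=0)
        synth = s.table.features[s.synthetic_mask]
        np.testing.assert_allclose(synth, np.broadcast_to([2.0, 3.0], synth.shape))

    def test_count_arithmetic(self, small_table):
        s = smote(small_table, k=3, rng_seed=1)
        assert s.n_synthetic == 6
        assert s.table.n_cases == s.table.n_controls == 10

    def test_synthetic_points_on_segments(self, rng):
        # every synthetic row must sit on the segment between its recorded
        # base and neighbour, coordinate-wise
        for seed in range(5):
            t = make_table(n_controls=30, n_cases=8, seed=seed)
            s = smote(t, k=5, rng_seed=seed)
            synth = s.table.features[s.synthetic_mask]
            base = t.features[s.provenance["base"]]
            nbr = t.features[s.provenance["neighbor"]]
            u = s.provenance["u"].to_numpy()[:, None]
            np.testing.assert_allclose(synth, base + u * (nbr - base), rtol=1e-12)
            lo = np.minimum(base, nbr) - 1e-12
            hi = np.maximum(base, nbr) + 1e-12
            assert np.all((synth >= lo) & (synth <= hi))

    def test_neighbors_are_among_k_nearest_minority(self):
        t = make_table(n_controls=20, n_cases=7, seed=2)
        k = 3
        s = smote(t, k=k, rng_seed=0)
        x_min = t.features[t.case_indices]
        d = cdist(x_min, x_min)
        np.fill_diagonal(d, np.inf)
        local = {g: i for i, g in enumerate(t.case_indices)}
        for b, nb in zip(s.provenance["base"], s.provenance["neighbor"]):
            order = sorted(range(len(x_min)),
                           key=lambda j: (d[local[b], j], j))[:k]
            assert local[nb] in order

    def test_base_rows_cycle_evenly(self):
        t = make_table(n_controls=20, n_cases=4, seed=0)
        s = smote(t, rng_seed=0)  # 16 synthetics over 4 bases -> 4 each
        counts = s.provenance["base"].value_counts()
        assert set(counts) == {4}

    def test_singleton_minority_fatal(self):
        t = LabeledTable(np.random.default_rng(0).normal(size=(5, 2)), [0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="gnus or random_upsample"):
            smote(t)


def _adasyn_allocation_oracle(table, k, G):
    """Brute-force r_i from an exhaustive distance sort + largest remainder."""
    x_min = table.features[table.case_indices]
    r = []
    for local, glob in enumerate(table.case_indices):
        d = np.sqrt(((table.features - x_min[local]) ** 2).sum(axis=1))
        order = sorted(range(table.n_samples), key=lambda j: (d[j], j))
        order = [j for j in order if j != glob][:k]
        r.append(sum(table.labels[j] == 0 for j in order) / k)
    r = np.array(r, dtype=float)
    w = r / r.sum()
    shares = G * w
    g = np.floor(shares).astype(int)
    frac = shares - g
    for j in sorted(range(len(g)), key=lambda i: (-frac[i], i))[: G - g.sum()]:
        g[j] += 1
    return g


class TestAdasyn:
    def test_allocation_matches_bruteforce_oracle(self):
        t = make_table(n_controls=60, n_cases=12, seed=4, shift=0.8)
        a = adasyn(t, k=5, rng_seed=0)
        got = a.provenance["base"].value_counts().reindex(t.case_indices, fill_value=0)
        expected = _adasyn_allocation_oracle(t, 5, 48)
        np.testing.assert_array_equal(got.to_numpy(), expected)
        assert a.n_synthetic == 48

    def test_separated_classes_fall_back_to_uniform(self):
        x = np.vstack([np.random.default_rng(0).normal(size=(12, 2)),
                       100 + np.random.default_rng(1).normal(scale=0.01, size=(4, 2))])
        t = LabeledTable(x, [0] * 12 + [1] * 4)
        with pytest.warns(UserWarning, match="uniform"):
            a = adasyn(t, k=3, rng_seed=0)
        assert a.table.n_cases == a.table.n_controls == 12
        counts = a.provenance["base"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_allocation_concentrates_on_surrounded_point(self):
        # one minority point deep inside the majority cloud takes everything
        rng = np.random.default_rng(3)
        maj = rng.normal(size=(20, 2))
        iso = 50 + rng.normal(scale=0.01, size=(4, 2))  # isolated minority cluster
        lone = np.zeros((1, 2))                         # surrounded by majority
        t = LabeledTable(np.vstack([maj, iso, lone]), [0] * 20 + [1] * 5)
        a = adasyn(t, k=3, rng_seed=0)
        counts = a.provenance["base"].value_counts()
        assert set(counts.index) == {24}
        assert counts.loc[24] == 15

    def test_beta_scales_target(self, small_table):
        a = adasyn(small_table, beta=0.5, rng_seed=0)
        assert a.n_synthetic == 3

    def test_synthetic_rows_on_minority_segments(self):
        t = make_table(n_controls=25, n_cases=9, seed=6)
        a = adasyn(t, k=4, rng_seed=2)
        synth = a.table.features[a.synthetic_mask]
        base = t.features[a.provenance["base"]]
        nbr = t.features[a.provenance["neighbor"]]
        u = a.provenance["u"].to_numpy()[:, None]
        np.testing.assert_allclose(synth, base + u * (nbr - base), rtol=1e-12)
        assert (t.labels[a.provenance["base"]] == 1).all()
        assert (t.labels[a.provenance["neighbor"]] == 1).all()

    def test_singleton_minority_fatal(self):
        t = LabeledTable(np.random.default_rng(0).normal(size=(5, 2)), [0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            adasyn(t)


class TestLargestRemainder:
    def test_exact_total_and_floor_property(self, rng):
        for _ in range(20):
            w = rng.random(6)
            w /= w.sum()
            total = int(rng.integers(1, 50))
            g = _largest_remainder(w, total)
            assert g.sum() == total
            assert np.all(g >= np.floor(total * w).astype(int))
            assert np.all(g <= np.floor(total * w).astype(int) + 1)


@pytest.mark.parametrize("method", ["upsample", "gnus", "smote", "adasyn"])
class TestCommonInvariants:
    def test_balanced_and_originals_preserved(self, method, ccbr_table):
        r = augment(ccbr_table, method, rng_seed=11)
        t = ccbr_table
        assert r.table.n_cases == r.table.n_controls
        assert r.n_synthetic == t.n_controls - t.n_cases
        np.testing.assert_array_equal(r.table.features[: t.n_samples], t.features)
        np.testing.assert_array_equal(r.table.labels[: t.n_samples], t.labels)
        assert (r.table.labels[r.synthetic_mask] == 1).all()

    def test_deterministic_under_seed(self, method, ccbr_table):
        r1 = augment(ccbr_table, method, rng_seed=5)
        r2 = augment(ccbr_table, method, rng_seed=5)
        np.testing.assert_array_equal(r1.table.features, r2.table.features)
        r3 = augment(ccbr_table, method, rng_seed=6)
        assert not np.array_equal(r1.table.features, r3.table.features)

    def test_synthetic_rows_within_minority_bounding_box(self, method, ccbr_table):
        r = augment(ccbr_table, method, rng_seed=3)
        synth = r.table.features[r.synthetic_mask]
        x_min = ccbr_table.features[ccbr_table.case_indices]
        lo, hi = x_min.min(axis=0), x_min.max(axis=0)
        if method == "gnus":
            mu = 0.001 * x_min.mean(axis=0)
            pad = np.abs(mu) + 6 * 0.001 * x_min.std(axis=0, ddof=1)
            lo, hi = lo - pad, hi + pad
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)
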