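"""TOM algebra, dynamic cut, eigengenes and module merging vs brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oligonet as on


def random_adjacency(rng, n):
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


def tom_bruteforce(A):
    """Direct triple-loop evaluation of unsigned topological overlap."""
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    k = B.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(B[i, u] * B[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + B[i, j]) / (min(k[i], k[j]) + 1 - B[i, j])
    return tom


def block_tom(sizes, within=0.9, between=0.05, rng=None, jitter=0.0):
    n = sum(sizes)
    labels = np.concatenate([np.full(s, k) for k, s in enumerate(sizes)])
    tom = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter:
        noise = rng.normal(0, jitter, (n, n))
        noise = (noise + noise.T) / 2
        tom = np.clip(tom + noise, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom, labels


class TestRescale:
    @pytest.mark.parametrize("rho,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5)])
    def test_affine_map(self, rho, expected):
        m = np.array([[1.0, rho], [rho, 1.0]])
        assert on.rescale_cor(m)[0, 1] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            on.rescale_cor(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestTOM:
    def test_complete_graph_is_all_ones(self):
        A = np.ones((6, 6))
        assert np.allclose(on.tom_similarity(A), 1.0)

    def test_empty_graph_has_zero_overlap(self):
        A = np.eye(5)
        tom = on.tom_similarity(A)
        assert np.allclose(tom[np.triu_indices(5, k=1)], 0.0)

    def test_matches_bruteforce_on_weighted_toy(self, rng):
        A = random_adjacency(rng, 4)
        assert np.allclose(on.tom_similarity(A), tom_bruteforce(A), atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_on_random_adjacencies(self, seed):
        A = random_adjacency(np.random.default_rng(seed), 8)
        tom = on.tom_similarity(A)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)


class TestScaleAndConsensus:
    def test_identity_calibration(self, rng):
        tom = on.tom_similarity(random_adjacency(rng, 10))
        out = on.scale_tom(tom, tom)
        assert np.allclose(out, tom)

    def test_quantile_matches_reference(self, rng):
        a = on.tom_similarity(random_adjacency(rng, 15))
        b = on.tom_similarity(random_adjacency(rng, 15)) ** 2
        out = on.scale_tom(b, a, q=0.95)
        iu = np.triu_indices(15, k=1)
        assert np.quantile(out[iu], 0.95, method="lower") == pytest.approx(
            np.quantile(a[iu], 0.95, method="lower"), abs=1e-12
        )

    def test_order_preserved(self, rng):
        a = on.tom_similarity(random_adjacency(rng, 12))
        b = on.tom_similarity(random_adjacency(rng, 12))
        out = on.scale_tom(b, a)
        iu = np.triu_indices(12, k=1)
        assert (np.argsort(out[iu]) == np.argsort(b[iu])).all()

    def test_degenerate_quantile_rejected(self):
        tom = np.ones((5, 5))
        with pytest.raises(ValueError, match="degenerate"):
            on.scale_tom(tom, tom)

    def test_consensus_is_elementwise_min(self, rng):
        a = on.tom_similarity(random_adjacency(rng, 9))
        b = on.tom_similarity(random_adjacency(rng, 9))
        cons = on.consensus_tom(a, b)
        assert np.array_equal(cons, np.minimum(a, b))
        assert (cons <= a).all() and (cons <= b).all()

    def test_single_year_connection_suppressed(self):
        a = np.array([[1.0, 0.9], [0.9, 1.0]])
        b = np.array([[1.0, 0.1], [0.1, 1.0]])
        assert on.consensus_tom(a, b)[0, 1] == pytest.approx(0.1)


class TestDetectModules:
    def test_two_perfect_blocks_recovered_exactly(self, rng):
        tom, labels = block_tom([20, 30], rng=rng, jitter=0.01)
        ms = on.detect_modules(tom)
        got = ms.assignment.to_numpy()
        assert ms.n_modules == 2
        # same partition as planted (labels may be permuted)
        for lab in (0, 1):
            assert len(set(got[labels == lab])) == 1
        assert set(got[labels == 0]) != set(got[labels == 1])

    def test_uniform_tom_flagged_degenerate(self):
        tom = np.full((30, 30), 0.4)
        np.fill_diagonal(tom, 1.0)
        ms = on.detect_modules(tom)
        assert ms.degenerate
        assert ms.n_modules <= 1

    def test_consensus_blocks_respect_both_years(self, rng):
        # pair connected in year A only is not co-assigned in the consensus
        tom_a, _ = block_tom([20, 20], rng=rng, jitter=0.01)
        tom_b, _ = block_tom([20, 20], within=0.04, between=0.04, rng=rng, jitter=0.005)
        cons = on.consensus_tom(tom_a, tom_b)
        ms = on.detect_modules(cons)
        assert ms.n_modules <= 1

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            on.detect_modules(np.eye(5), minClusterSize=10)

    def test_invalid_deepsplit_rejected(self):
        with pytest.raises(ValueError):
            on.detect_modules(np.eye(20), deepSplit=7)


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        x = pd.DataFrame([[5, 5, 5, 5]])
        assert np.allclose(on.clr_transform(x).to_numpy(), 0.0, atol=1e-6)

    def test_rows_centered(self, rng):
        x = pd.DataFrame(rng.integers(1, 100, (10, 8)))
        clr = on.clr_transform(x)
        assert np.abs(clr.sum(axis=1)).max() < 1e-9

    def test_toy_three_part_hand_computed(self):
        x = pd.DataFrame([[2, 3, 5]])
        p = np.array([0.2, 0.3, 0.5]) + 1e-6
        expected = np.log(p) - np.log(p).mean()
        assert np.allclose(on.clr_transform(x).to_numpy()[0], expected)

    def test_matches_skbio_clr(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = rng.integers(1, 50, (5, 6)).astype(float)
        p = x / x.sum(axis=1, keepdims=True) + 1e-6
        expected = skbio_comp.clr(p)
        assert np.allclose(on.clr_transform(pd.DataFrame(x)).to_numpy(), expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            on.clr_transform(pd.DataFrame([[0, 0, 0]]))


def power_iteration_pc1(Xc, iters=2000):
    """Independent dominant-eigenvector solver for the covariance."""
    C = Xc.T @ Xc
    v = np.ones(C.shape[0]) / np.sqrt(C.shape[0])
    for _ in range(iters):
        v = C @ v
        v /= np.linalg.norm(v)
    return v


class TestEigengene:
    def test_rank_one_module_tracks_shared_profile(self, rng):
        profile = rng.normal(size=20)
        X = pd.DataFrame(np.outer(profile, rng.uniform(0.5, 2.0, 6)))
        me, loading = on.module_eigengene(X, list(X.columns))
        r = np.corrcoef(me, profile - profile.mean())[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert np.linalg.norm(loading) == pytest.approx(1.0)

    def test_orientation_positive_with_mean_profile(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        for data in (X, -X):
            me, _ = on.module_eigengene(data, list(data.columns))
            mean_profile = (data - data.mean()).mean(axis=1)
            assert np.corrcoef(me, mean_profile)[0, 1] >= 0

    def test_matches_power_iteration_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 7)))
        me, loading = on.module_eigengene(X, list(X.columns))
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        v = power_iteration_pc1(Xc)
        if np.dot(v, loading) < 0:
            v = -v
        assert np.allclose(loading, v, atol=1e-6)
        assert np.allclose(me, Xc @ v, atol=1e-6)

    def test_constant_submatrix_rejected(self):
        X = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(ValueError, match="constant"):
            on.module_eigengene(X, list(X.columns))


def planted_me_clr(rng, profiles, module_of, n_samples, noise=0.2):
    """clr-like data: module members follow their module profile plus noise."""
    cols = {}
    for taxon, m in module_of.items():
        cols[taxon] = profiles[m] + rng.normal(0, noise, n_samples)
    df = pd.DataFrame(cols)
    return df - df.mean()


class TestMergeModules:
    def _module_set(self, module_of):
        return on.ModuleSet(assignment=pd.Series(module_of))

    def test_identical_eigengenes_merge(self, rng):
        n = 30
        shared = rng.normal(size=n)
        profiles = {1: shared, 2: shared, 3: rng.normal(size=n)}
        module_of = {f"t{i}": (i % 3) + 1 for i in range(30)}
        clr = {
            y: planted_me_clr(np.random.default_rng(y), profiles, module_of, n)
            for y in (1, 2)
        }
        merged = on.merge_modules(self._module_set(module_of), clr)
        assert merged.n_modules == 2

    def test_anticorrelated_eigengenes_never_merge(self, rng):
        n = 30
        base = rng.normal(size=n)
        profiles = {1: base, 2: -base}
        module_of = {f"t{i}": (i % 2) + 1 for i in range(20)}
        clr = {
            y: planted_me_clr(np.random.default_rng(10 + y), profiles, module_of, n)
            for y in (1, 2)
        }
        merged = on.merge_modules(self._module_set(module_of), clr)
        assert merged.n_modules == 2

    def test_eleven_modules_with_four_shared_drivers_merge_to_seven(self):
        # 11 planted modules; modules (1,2), (3,4), (5,6), (7,8) share a
        # driver pairwise, drivers are mutually near-orthogonal
        rng = np.random.default_rng(42)
        n = 48
        raw = rng.normal(size=(n, 7))
        q, _ = np.linalg.qr(raw)         # orthogonal driver profiles
        drivers = {k: q[:, k] * np.sqrt(n) for k in range(7)}
        driver_of = {1: 0, 2: 0, 3: 1, 4: 1, 5: 2, 6: 2, 7: 3, 8: 3,
                     9: 4, 10: 5, 11: 6}
        profiles = {m: drivers[d] for m, d in driver_of.items()}
        module_of = {}
        for m in range(1, 12):
            for j in range(8):
                module_of[f"m{m}_t{j}"] = m
        clr = {
            y: planted_me_clr(np.random.default_rng(100 + y), profiles, module_of, n)
            for y in (1, 2)
        }
        merged = on.merge_modules(
            self._module_set(module_of), clr, cutHeight=0.25
        )
        assert merged.n_modules == 7
        # driver-sharing pairs land in the same merged module
        assign = merged.assignment
        for a, b in [(1, 2), (3, 4), (5, 6), (7, 8)]:
            assert assign[f"m{a}_t0"] == assign[f"m{b}_t0"]

    def test_eigengenes_recomputed_after_merge(self, rng):
        n = 30
        shared = rng.normal(size=n)
        profiles = {1: shared, 2: shared}
        module_of = {f"t{i}": (i % 2) + 1 for i in range(20)}
        clr = {
            y: planted_me_clr(np.random.default_rng(20 + y), profiles, module_of, n)
            for y in (1, 2)
        }
        merged = on.merge_modules(self._module_set(module_of), clr)
        assert merged.n_modules == 1
        me = merged.eigengenes[1].iloc[:, 0]
        assert me.shape[0] == n
        assert len(merged.merge_history) == 1
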