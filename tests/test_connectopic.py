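import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

import gradmap as gm
from gradmap.connectopic import (
    ConnectivityMode,
    align_mode,
    compute_fingerprints,
    eta2_similarity,
    group_similarity,
    laplacian_eigenmaps,
    map_subject,
    reduce_reference,
)
from gradmap.imaging_io import extract_timeseries


def eta2_bruteforce(C):
    """Independent per-pair loop evaluation of the η² coefficient."""
    V, r = C.shape
    S = np.empty((V, V))
    for a in range(V):
        for b in range(V):
            x, y = C[a], C[b]
            m = (x + y) / 2.0
            M = np.mean(np.concatenate([x, y]))
            num = np.sum((x - m) ** 2 + (y - m) ** 2)
            den = np.sum((x - M) ** 2 + (y - M) ** 2)
            S[a, b] = 1.0 - num / den if den > 0 else 1.0
    return S


def eigenmaps_oracle(S, n_modes):
    """Dense generalized eigendecomposition via the non-symmetric solver."""
    W = S.copy()
    np.fill_diagonal(W, 0.0)
    D = np.diag(W.sum(axis=1))
    vals, vecs = scipy.linalg.eig(np.diag(1.0 / W.sum(axis=1)) @ (D - W))
    order = np.argsort(vals.real)
    out = []
    for idx in order[1:n_modes + 1]:
        v = vecs[:, idx].real
        d = W.sum(axis=1)
        v = v - (d @ v) / d.sum()
        out.append(v / np.linalg.norm(v))
    return np.array(out).T, np.sort(vals.real)[1:n_modes + 1]


class TestReduceReference:
    def test_rank_forced_by_design(self, rng):
        basis = np.linalg.qr(rng.standard_normal((50, 5)))[0]
        B = basis @ rng.standard_normal((5, 200))
        ref = reduce_reference(B)
        assert ref.rank == 5

    def test_lossless_reconstruction(self, rng):
        B = rng.standard_normal((40, 90))
        B -= B.mean(axis=0)
        ref = reduce_reference(B)
        proj = ref.components @ (ref.components.T @ B)
        assert np.linalg.norm(B - proj) / np.linalg.norm(B) <= 1e-8

    def test_orthonormal_components(self, rng):
        ref = reduce_reference(rng.standard_normal((30, 80)))
        gram = ref.components.T @ ref.components
        np.testing.assert_allclose(gram, np.eye(ref.rank), atol=1e-8)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zeros"):
            reduce_reference(np.zeros((10, 20)))

    def test_similarity_invariant_to_reduction_route(self, rng):
        # fingerprints against the SVD basis give the same η² as against the
        # identical compression computed by an independent second routine
        # (eigendecomposition of B Bᵀ); per-component signs are aligned since
        # η² is not sign-invariant
        t, W, V = 100, 300, 15
        B = rng.standard_normal((t, W))
        B -= B.mean(axis=0)
        A = rng.standard_normal((t, V))
        ref1 = reduce_reference(B)
        S1 = eta2_similarity(compute_fingerprints(A, ref1))
        evals, evecs = scipy.linalg.eigh(B @ B.T)
        order = np.argsort(evals)[::-1][:ref1.rank]
        U2 = evecs[:, order]
        signs = np.sign(np.einsum("tr,tr->r", U2, ref1.components))
        C2 = compute_fingerprints(A, type(ref1)(
            components=U2 * signs,
            singular_values=np.sqrt(np.maximum(evals[order], 0))))
        np.testing.assert_allclose(S1, eta2_similarity(C2), atol=1e-8)


class TestFingerprints:
    def test_voxel_equal_to_component(self, rng):
        U = np.linalg.qr(rng.standard_normal((60, 5)))[0]
        ref = reduce_reference(U @ np.diag([5, 4, 3, 2, 1]) @
                               rng.standard_normal((5, 50)))
        A = ref.components[:, [3]].copy()
        C = compute_fingerprints(A, ref)
        assert C[0, 3] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_voxel_near_zero(self, rng):
        B = rng.standard_normal((80, 40))
        ref = reduce_reference(B)
        # a series orthogonal to the whole column space of B
        q, _ = np.linalg.qr(np.c_[ref.components,
                                  rng.standard_normal((80, 1))])
        C = compute_fingerprints(q[:, [-1]], ref)
        assert np.abs(C).max() < 0.2  # demeaning perturbs exact orthogonality

    def test_matches_direct_correlation_formula(self, rng):
        A = rng.standard_normal((30, 5))
        ref = reduce_reference(rng.standard_normal((30, 12)))
        C = compute_fingerprints(A, ref)
        for v in range(5):
            for j in range(ref.rank):
                r = pearsonr(A[:, v], ref.components[:, j])[0]
                assert C[v, j] == pytest.approx(r, abs=1e-12)


class TestEta2:
    def test_identical_profiles(self, rng):
        C = np.tile(rng.standard_normal(6), (4, 1))
        S = eta2_similarity(C)
        np.testing.assert_allclose(S, 1.0)

    def test_mirrored_profiles_give_zero(self):
        # x and y symmetric about their pairwise means: within = total
        x = np.array([1.0, 2.0, 3.0, 4.0])
        C = np.vstack([x, -x])
        S = eta2_similarity(C)
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        C = rng.standard_normal((20, 5))
        np.testing.assert_allclose(eta2_similarity(C), eta2_bruteforce(C),
                                   atol=1e-12)

    def test_not_invariant_to_single_profile_shift(self, rng):
        # negative control: unlike correlation, η² changes when only one of
        # the two profiles is shifted (a joint shift of both cancels in the
        # grand mean and leaves η² unchanged)
        C = rng.standard_normal((4, 6))
        S1 = eta2_similarity(C)
        C2 = C.copy()
        C2[0] += 5.0
        S2 = eta2_similarity(C2)
        assert not np.allclose(S1[0, 1], S2[0, 1], atol=1e-3)
        np.testing.assert_allclose(eta2_similarity(C + 5.0), S1, atol=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetric_and_bounded(self, seed):
        C = np.random.default_rng(seed).standard_normal((8, 4))
        S = eta2_similarity(C)
        assert np.max(np.abs(S - S.T)) <= 1e-10
        assert S.min() >= 0.0 and S.max() <= 1.0
        np.testing.assert_allclose(np.diag(S), 1.0)


class TestLaplacianEigenmaps:
    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            C = rng.standard_normal((30, 6))
            S = eta2_similarity(C)
            modes = laplacian_eigenmaps(S, 4)
            oracle_vecs, oracle_vals = eigenmaps_oracle(S, 4)
            for m, (ov, oval) in enumerate(zip(oracle_vecs.T, oracle_vals)):
                assert modes[m].eigenvalue == pytest.approx(oval, abs=1e-8)
                dot = abs(modes[m].values @ ov)
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_two_block_structure_separated_by_sign(self):
        V = 20
        S = np.full((V, V), 0.01)
        S[:10, :10] = 0.9
        S[10:, 10:] = 0.9
        np.fill_diagonal(S, 1.0)
        modes = laplacian_eigenmaps(S, 1)
        signs = np.sign(modes[0].values)
        assert len(set(signs[:10])) == 1 and len(set(signs[10:])) == 1
        assert signs[0] != signs[-1]

    def test_chain_structure_monotone(self):
        V = 25
        S = np.eye(V)
        for i in range(V - 1):
            S[i, i + 1] = S[i + 1, i] = 0.9
        S += 1e-4  # weak background keeps the graph connected
        modes = laplacian_eigenmaps(S, 1)
        diffs = np.diff(modes[0].values)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_eigenvalues_nondecreasing_and_trivial_discarded(self, rng):
        S = eta2_similarity(rng.standard_normal((20, 5)))
        modes = laplacian_eigenmaps(S, 5)
        eigs = [m.eigenvalue for m in modes]
        assert np.all(np.diff(eigs) >= -1e-12)
        assert all(e > 1e-10 for e in eigs)
        # D-weighted mean of each mode is zero
        W = S.copy()
        np.fill_diagonal(W, 0.0)
        d = W.sum(axis=1)
        for m in modes:
            assert abs(d @ m.values) / d.sum() <= 1e-8

    def test_disconnected_graph_errors(self):
        S = np.eye(6)
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            laplacian_eigenmaps(S, 1)

    def test_too_many_modes_errors(self, rng):
        S = eta2_similarity(rng.standard_normal((5, 4)))
        with pytest.raises(ValueError, match="n_modes"):
            laplacian_eigenmaps(S, 5)

    def test_permutation_equivariance(self, rng):
        C = rng.standard_normal((18, 5))
        S = eta2_similarity(C)
        perm = rng.permutation(18)
        S_perm = S[np.ix_(perm, perm)]
        modes = laplacian_eigenmaps(S, 2)
        modes_perm = laplacian_eigenmaps(S_perm, 2)
        for m, mp in zip(modes, modes_perm):
            v = m.values[perm]
            v = v if abs(v @ mp.values - 1) < abs(v @ mp.values + 1) else -v
            np.testing.assert_allclose(v, mp.values, atol=1e-8)


class TestAlignMode:
    def _mode(self, values, order=0):
        v = np.asarray(values, float)
        return ConnectivityMode(order=order, values=v / np.linalg.norm(v),
                                eigenvalue=0.5)

    def test_negative_correlation_flipped(self, rng):
        ref = self._mode(rng.standard_normal(20))
        noisy = -0.8 * ref.values + 0.2 * rng.standard_normal(20)
        mode = self._mode(noisy)
        out = align_mode(mode, ref)
        assert pearsonr(out.values, ref.values)[0] > 0
        assert out.aligned_to == "group"

    def test_positive_correlation_unchanged(self, rng):
        ref = self._mode(rng.standard_normal(20))
        mode = self._mode(0.3 * ref.values + rng.standard_normal(20))
        expect = mode.values.copy()
        if pearsonr(mode.values, ref.values)[0] < 0:
            expect = -expect
        out = align_mode(mode, ref)
        np.testing.assert_array_equal(out.values, expect)

    def test_exact_negation_returns_reference(self, rng):
        ref = self._mode(rng.standard_normal(20))
        mode = ConnectivityMode(order=0, values=-ref.values, eigenvalue=0.5)
        out = align_mode(mode, ref)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-15)

    def test_zero_variance_errors(self):
        ref = self._mode(np.arange(5.0))
        flat = ConnectivityMode(order=0, values=np.ones(5), eigenvalue=0.1)
        with pytest.raises(ValueError, match="variance"):
            align_mode(flat, ref)


class TestGroupSimilarity:
    def test_mean_of_identical_is_identity(self, rng):
        S = eta2_similarity(rng.standard_normal((10, 4)))
        np.testing.assert_allclose(group_similarity([S, S, S]), S, atol=1e-15)

    def test_two_subject_elementwise_mean(self, rng):
        S1 = eta2_similarity(rng.standard_normal((8, 4)))
        S2 = eta2_similarity(rng.standard_normal((8, 4)))
        np.testing.assert_allclose(group_similarity([S1, S2]), (S1 + S2) / 2,
                                   atol=1e-15)

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            group_similarity([np.eye(4), np.eye(5)])


class TestMapSubject:
    def test_composition_identity(self, small_scene, small_bold):
        bold, brain = small_bold
        roi = small_scene.roi_specs[0]
        modes = map_subject(bold, roi, brain, 2)
        pair = extract_timeseries(bold, roi, brain)
        ref = reduce_reference(pair.B)
        S = eta2_similarity(compute_fingerprints(pair.A, ref))
        manual = laplacian_eigenmaps(S, 2)
        for m, mm in zip(modes, manual):
            np.testing.assert_array_equal(m.values, mm.values)

    def test_deterministic(self, small_scene, small_bold):
        bold, brain = small_bold
        roi = small_scene.roi_specs[0]
        a = map_subject(bold, roi, brain, 2)
        b = map_subject(bold, roi, brain, 2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_two_planted_gradients_recovered(self, two_gradient_scene):
        scene = two_gradient_scene
        bold, brain = gm.synthesize_bold(scene, t=300, seed=42)
        modes = map_subject(bold, scene.roi_specs[0], brain, 3)
        G = scene.planted_gradients[0]
        for k in range(2):
            r = pearsonr(modes[k].values, G[:, k])[0]
            assert abs(r) >= 0.9

    def test_modes_near_orthogonal(self, two_gradient_scene):
        scene = two_gradient_scene
        bold, brain = gm.synthesize_bold(scene, t=300, seed=43)
        modes = map_subject(bold, scene.roi_specs[0], brain, 3)
        for a in range(3):
            for b in range(a + 1, 3):
                r = pearsonr(modes[a].values, modes[b].values)[0]
                assert abs(r) <= 0.15
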