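import itertools

import numpy as np
import pytest

from proteoscreen import smbplsr as smb
from proteoscreen.synthetic_data import make_grouped_response


def brute_force_objective(X, Y, k_features, k_drugs):
    """Exhaustive support enumeration: best sum cov^2 over all supports.

    For one block the optimum on a fixed support pair is the leading
    singular value of the corresponding submatrix of the cross-covariance.
    """
    n = X.shape[0]
    C = (X - X.mean(0)).T @ (Y - Y.mean(0)) / (n - 1)
    best = -np.inf
    for su in itertools.combinations(range(X.shape[1]), k_features):
        for sv in itertools.combinations(range(Y.shape[1]), k_drugs):
            s1 = np.linalg.svd(C[np.ix_(su, sv)], compute_uv=False)[0]
            best = max(best, s1**2)
    return best


class TestFitComponent:
    def test_dense_limit_matches_svd(self, rng):
        X = rng.normal(size=(10, 5))
        Y = rng.normal(size=(10, 4))
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        comp = smb.fit_component(data, k_drugs=4, k_features=5, tol=1e-12,
                                 max_iter=5000)
        C = data.X_blocks[0].T @ data.Y / 9
        U, S, Vt = np.linalg.svd(C)
        assert comp.objective == pytest.approx(S[0] ** 2, rel=1e-6)
        assert np.allclose(np.abs(comp.u[0]), np.abs(U[:, 0]), atol=1e-6)
        assert np.allclose(np.abs(comp.v), np.abs(Vt[0]), atol=1e-6)

    @pytest.mark.parametrize("n_features,n_drugs", [(3, 2), (6, 4)])
    def test_matches_brute_force_on_tiny_instances(self, n_features, n_drugs):
        for k_f, k_d, seed in itertools.product((1, 2), (1, 2), range(3)):
            r = np.random.default_rng(1000 * seed + 10 * n_features + n_drugs)
            X = r.normal(size=(4, n_features))
            Y = r.normal(size=(4, n_drugs))
            data = smb.SMBPLSRInput.from_matrices([X], Y)
            comp = smb.fit_component(data, k_drugs=k_d, k_features=k_f,
                                     tol=1e-10, max_iter=2000)
            oracle = brute_force_objective(X, Y, k_f, k_d)
            assert comp.objective == pytest.approx(oracle, rel=1e-6)

    def test_single_informative_drug_column_forces_support(self, rng):
        n = 8
        X = rng.normal(size=(n, 5))
        Y = np.zeros((n, 3))
        Y[:, 1] = X[:, 0] + 0.01 * rng.normal(size=n)
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        comp = smb.fit_component(data, k_drugs=1, k_features=5)
        assert np.flatnonzero(comp.v).tolist() == [1]

    def test_cardinalities_and_norms(self, rng):
        X1 = rng.normal(size=(12, 20))
        X2 = rng.normal(size=(12, 30))
        Y = rng.normal(size=(12, 8))
        data = smb.SMBPLSRInput.from_matrices([X1, X2], Y)
        comp = smb.fit_component(data, k_drugs=3, k_features=10)
        assert np.count_nonzero(comp.v) == 3
        assert sum(np.count_nonzero(u) for u in comp.u) == 10
        assert np.linalg.norm(comp.v) == pytest.approx(1.0)
        for u in comp.u:
            if np.count_nonzero(u):
                assert np.linalg.norm(u) == pytest.approx(1.0)

    def test_sign_convention_dominant_drug_positive(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 4))
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        comp = smb.fit_component(data, k_drugs=2, k_features=3)
        assert comp.v[np.argmax(np.abs(comp.v))] > 0


class TestDeflate:
    def test_scores_orthogonal_to_deflated_block(self, rng):
        X = rng.normal(size=(15, 12))
        Y = rng.normal(size=(15, 5))
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        comp = smb.fit_component(data, k_drugs=2, k_features=4)
        out = smb.deflate(data, comp)
        assert np.allclose(comp.t[0] @ out.X_blocks[0], 0, atol=1e-9)

    def test_rank_one_signal_exhausted_after_one_component(self, rng):
        z = rng.normal(size=10)
        X = np.outer(z, rng.normal(size=6))
        Y = np.outer(z, rng.normal(size=4))
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        comp1 = smb.fit_component(data, k_drugs=4, k_features=6)
        deflated = smb.deflate(data, comp1)
        comp2 = smb.fit_component(deflated, k_drugs=4, k_features=6)
        assert comp2.objective <= 1e-12 * comp1.objective

    def test_zero_component_is_identity(self, rng):
        X = rng.normal(size=(8, 4))
        Y = rng.normal(size=(8, 3))
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        comp = smb.fit_component(data, k_drugs=1, k_features=1)
        comp.t = [np.zeros(8)]
        comp.s = np.zeros(8)
        out = smb.deflate(data, comp)
        assert np.allclose(out.X_blocks[0], data.X_blocks[0])
        assert np.allclose(out.Y, data.Y)


class TestFit:
    def test_planted_group_recovery(self):
        recovered = 0
        for seed in range(10):
            X_blocks, Y, planted = make_grouped_response(seed=seed)
            data = smb.SMBPLSRInput.from_matrices(X_blocks, Y)
            model = smb.fit(data, n_components=2, k_drugs=6, k_features=10)
            found = [set(np.flatnonzero(c.v)) for c in model.components]
            ok = True
            for group in planted["drug_groups"]:
                g = set(group)
                jac = max(len(g & f) / len(g | f) for f in found)
                ok = ok and jac >= 0.8
            recovered += ok
        assert recovered == 10

    def test_sample_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 10))
        Y = rng.normal(size=(12, 5))
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        model = smb.fit(data, n_components=2, k_drugs=2, k_features=4)
        perm = rng.permutation(12)
        data_p = smb.SMBPLSRInput.from_matrices([X[perm]], Y[perm])
        model_p = smb.fit(data_p, n_components=2, k_drugs=2, k_features=4)
        for c, cp in zip(model.components, model_p.components):
            assert np.allclose(cp.v, c.v, atol=1e-8)
            assert np.allclose(cp.u[0], c.u[0], atol=1e-8)
            assert np.allclose(cp.s, c.s[perm], atol=1e-8)

    def test_default_configuration_counts(self, rng):
        X1 = rng.normal(size=(17, 120))
        X2 = rng.normal(size=(17, 200))
        Y = rng.normal(size=(17, 30))
        data = smb.SMBPLSRInput.from_matrices([X1, X2], Y)
        model = smb.fit(data)  # 12 components, 6 drugs, 50 features
        assert len(model) == 12
        for comp in model.components:
            assert len(comp.selected_drugs) == 6
            assert len(comp.selected_features) == 50

    def test_rank_deficient_response_stops_early(self, rng):
        z = rng.normal(size=6)
        X = rng.normal(size=(6, 4))
        Y = np.outer(z, np.ones(3)) * 0  # zero response
        data = smb.SMBPLSRInput.from_matrices([X], Y)
        model = smb.fit(data, n_components=3, k_drugs=1, k_features=1)
        assert len(model) == 0


class TestBudgetAllocation:
    def test_proportional_with_caps(self):
        alloc = smb._allocate_budget(np.array([3.0, 1.0]), np.array([2, 10]), 8)
        assert alloc.sum() == 8
        assert alloc[0] <= 2

    def test_total_never_exceeds_dimensions(self):
        alloc = smb._allocate_budget(np.array([1.0, 1.0]), np.array([2, 3]), 50)
        assert alloc.tolist() == [2, 3]
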