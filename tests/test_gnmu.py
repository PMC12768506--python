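import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mrsifp.basis import default_basis
from mrsifp.gnmu import (
    feasibility_violation,
    gnmu_decompose,
    project_contributions,
    source_composition,
)
from mrsifp.synthetic import planted_sources_cohort


def rank_one_oracle(X: np.ndarray, levels: int = 20) -> float:
    """Exhaustive grid search over rank-one underapproximations.

    Candidate spectra w are enumerated on a grid with one component pinned
    at 1 (the scale is absorbed by h). For fixed w the optimal feasible h
    has a closed form per column: the unconstrained least-squares
    coefficient clipped to the largest value keeping h_j * w <= x_j.
    Returns the best Frobenius objective found.
    """
    m, n = X.shape
    grid = np.linspace(0.0, 1.0, levels + 1)
    cands = []
    for pin in range(m):
        rest = np.array(np.meshgrid(*[grid] * (m - 1))).reshape(m - 1, -1).T
        W = np.insert(rest, pin, 1.0, axis=1)
        cands.append(W)
    W = np.unique(np.vstack(cands), axis=0)  # K x m
    wsq = (W**2).sum(axis=1)  # K
    cross = W @ X  # K x n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(W[:, :, None] > 0,
                         X[None, :, :] / np.where(W[:, :, None] > 0, W[:, :, None], 1.0),
                         np.inf)
    ub = ratio.min(axis=1)  # K x n
    h = np.clip(cross / wsq[:, None], 0.0, ub)
    obj2 = (X**2).sum() - (2 * h * cross - h**2 * wsq[:, None]).sum(axis=1)
    return float(np.sqrt(max(obj2.min(), 0.0)))


class TestRankOne:
    def test_all_ones_is_exact(self):
        res = gnmu_decompose(np.ones((2, 2)), r=1)
        assert res.residual == pytest.approx(0.0, abs=1e-9)

    def test_identity_residual_one(self):
        """A rank-one non-negative underapproximation of the 2x2 identity can
        capture only one diagonal element; the optimal residual is 1."""
        res = gnmu_decompose(np.eye(2), r=1)
        assert res.residual == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("m", [3, 4])
    def test_matches_grid_oracle(self, m):
        rng = np.random.default_rng(2024 + m)
        for _ in range(10):
            X = rng.integers(0, 6, size=(m, m)).astype(float)
            if X.max() == 0:
                continue
            ours = gnmu_decompose(X, r=1).residual
            oracle = rank_one_oracle(X)
            assert ours <= oracle * 1.01 + 1e-9


class TestDecomposition:
    def test_validation(self):
        with pytest.raises(ValueError):
            gnmu_decompose(np.ones((3, 3)), r=4)
        with pytest.raises(ValueError):
            gnmu_decompose(np.full((3, 3), np.nan), r=1)
        with pytest.raises(ValueError):
            gnmu_decompose(-np.ones((3, 3)), r=1)

    @pytest.mark.parametrize("mode", ["global", "recursive"])
    def test_underapproximation_invariant(self, mode, rng):
        X = rng.uniform(0, 1, (40, 30))
        res = gnmu_decompose(X, r=4, mode=mode, seed=0)
        assert feasibility_violation(X, res.W, res.H) <= 1e-8 * X.max()
        assert res.W.min() >= 0 and res.H.min() >= 0

    def test_unit_max_columns_and_ordering(self, rng):
        X = rng.uniform(0, 1, (40, 30))
        res = gnmu_decompose(X, r=3, seed=0)
        live = res.W.max(axis=0) > 0
        np.testing.assert_allclose(res.W.max(axis=0)[live], 1.0)
        totals = res.H.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-9)

    def test_objective_monotone(self, rng):
        X = rng.uniform(0, 1, (30, 25))
        res = gnmu_decompose(X, r=3, seed=0)
        hist = res.objective_history
        assert np.all(np.diff(hist) <= 1e-10 * np.maximum(hist[:-1], 1.0))

    def test_seeded_determinism(self, rng):
        X = rng.uniform(0, 1, (30, 25))
        a = gnmu_decompose(X, r=3, seed=5, init="random")
        b = gnmu_decompose(X, r=3, seed=5, init="random")
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_planted_factor_recovery(self):
        """Three planted metabolite-like sources are recovered with matched
        cosine similarity >= 0.95 at SNR 20."""
        b = default_basis(0.5, 4.2, 256)
        W_true = b.spectra[:, [0, 3, 6]]  # NAA, mI, 2HG
        X0, _, H0 = planted_sources_cohort(W_true, 0.3, 500, 0.0, seed=0)
        noise_sd = np.sqrt((W_true @ H0).var()) / 20.0
        X, Wt, _ = planted_sources_cohort(W_true, 0.3, 500, noise_sd, seed=0)
        res = gnmu_decompose(X, r=3, seed=0)
        A = res.W / np.linalg.norm(res.W, axis=0, keepdims=True)
        B = Wt / np.linalg.norm(Wt, axis=0, keepdims=True)
        C = A.T @ B
        rows, cols = linear_sum_assignment(-C)
        assert C[rows, cols].min() >= 0.95


class TestProjectContributions:
    def test_column_of_w_gives_unit_vector(self, rng):
        W = rng.uniform(0, 1, (20, 3))
        H = project_contributions(W, W[:, 1])
        np.testing.assert_allclose(H[:, 0], [0, 1, 0], atol=1e-10)

    def test_zero_spectrum_gives_zero(self, rng):
        W = rng.uniform(0, 1, (20, 3))
        assert project_contributions(W, np.zeros(20)).max() == 0

    def test_disjoint_supports_closed_form(self):
        W = np.zeros((10, 2))
        W[:5, 0] = 1.0
        W[5:, 1] = 1.0
        x = 2.0 * W[:, 0] + 3.0 * W[:, 1]
        np.testing.assert_allclose(project_contributions(W, x)[:, 0], [2.0, 3.0])

    def test_grid_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            project_contributions(rng.uniform(0, 1, (20, 3)), np.zeros((19, 2)))


class TestSourceComposition:
    def test_pure_basis_spectrum_is_100pct(self, basis):
        W = basis.spectra[:, [2]]  # Cho
        frac = source_composition(W, basis)
        assert frac[0, basis.names.index("Cho")] == pytest.approx(100.0, abs=1e-6)
        assert frac[0].sum() == pytest.approx(100.0, abs=0.01)

    def test_equal_mixture_with_disjoint_supports(self):
        # NAA (2.01) and Cho (3.20) barely overlap at 0.04 ppm linewidth
        b = default_basis(0.5, 4.2, 1024, linewidth=0.02)
        i, j = b.names.index("NAA"), b.names.index("Cho")
        integ = b.integrals()
        W = (b.spectra[:, [i]] / integ[i] + b.spectra[:, [j]] / integ[j])
        frac = source_composition(W, b)
        assert frac[0, i] == pytest.approx(50.0, abs=2.0)
        assert frac[0, j] == pytest.approx(50.0, abs=2.0)

    def test_planted_dominant_metabolite_recovered(self):
        b = default_basis(0.5, 4.2, 256)
        picks = [0, 3, 6]
        W_true = b.spectra[:, picks]
        X, _, _ = planted_sources_cohort(W_true, 0.3, 300, 0.05, seed=4)
        res = gnmu_decompose(X, r=3, seed=4)
        frac = source_composition(res.W, b)
        dominants = set(np.argmax(frac, axis=1))
        assert dominants == set(picks)

    def test_rows_sum_to_100(self, basis, rng):
        W = rng.uniform(0, 1, (basis.n_points, 4))
        frac = source_composition(W, basis)
        np.testing.assert_allclose(frac.sum(axis=1), 100.0, atol=0.01)
        assert frac.min() >= 0
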