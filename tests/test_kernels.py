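import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gkblup as gk
from gkblup.io import ValidationError
from gkblup.kernels import DegenerateDistanceError, GaussianKernelizer


def _markers(codes):
    codes = np.asarray(codes)
    ids = tuple(f"L{i}" for i in range(codes.shape[0]))
    return gk.MarkerMatrix(ids, codes)


class TestDistances:
    def test_single_pair_defines_the_scale(self):
        d = gk.squared_distance_matrix(_markers([[0, 0], [2, 2]]))
        assert d.scale_factor == 8.0
        np.testing.assert_allclose(d.d2, [[0, 1], [1, 0]])

    def test_three_line_scaling(self):
        # raw squared distances {8, 2, 2} -> scaled {1, 0.25, 0.25}
        d = gk.squared_distance_matrix(_markers([[0, 0], [2, 2], [1, 1]]))
        assert d.scale_factor == 8.0
        np.testing.assert_allclose(sorted(d.d2[np.triu_indices(3, 1)]), [0.25, 0.25, 1.0])

    def test_identical_lines_degenerate(self):
        with pytest.raises(DegenerateDistanceError):
            gk.squared_distance_matrix(_markers([[1, 2], [1, 2]]))

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(0)
        d = gk.squared_distance_matrix(_markers(rng.integers(0, 3, size=(12, 40))))
        assert d.d2.max() == pytest.approx(1.0)
        assert d.d2.min() == 0.0
        np.testing.assert_allclose(d.d2, d.d2.T)


class TestGaussianKernel:
    def test_power_form(self):
        d = gk.DistanceMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), 1.0, ("a", "b"))
        k = gk.gaussian_kernel(d, 0.5)
        assert k.values[0, 1] == pytest.approx(0.25)
        np.testing.assert_allclose(np.diag(k.values), 1.0)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.2, 1.5])
    def test_bandwidth_domain(self, rho):
        d = gk.DistanceMatrix(np.zeros((2, 2)), 1.0, ("a", "b"))
        with pytest.raises(ValueError):
            gk.gaussian_kernel(d, rho)

    def test_matches_gamma_parameterization(self):
        # rho^{d^2} must equal exp(-gamma d^2) with gamma = -log rho
        rng = np.random.default_rng(3)
        d2 = rng.uniform(0, 1, size=(5, 5))
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0.0)
        d = gk.DistanceMatrix(d2, 1.0, tuple("abcde"))
        for rho in (0.05, 0.37, 0.9):
            gamma = -math.log(rho)
            np.testing.assert_allclose(gk.gaussian_kernel(d, rho).values, np.exp(-gamma * d2))

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.02, 0.95), st.floats(0.02, 0.95))
    def test_monotone_in_rho(self, r1, r2):
        lo, hi = min(r1, r2), max(r1, r2)
        if hi - lo < 1e-6:
            hi = min(0.99, hi + 0.01)
        d = gk.DistanceMatrix(np.array([[0.0, 0.6], [0.6, 0.0]]), 1.0, ("a", "b"))
        assert gk.gaussian_kernel(d, lo).values[0, 1] < gk.gaussian_kernel(d, hi).values[0, 1]

    def test_limit_rho_to_one_is_all_ones(self):
        rng = np.random.default_rng(5)
        d = gk.squared_distance_matrix(_markers(rng.integers(0, 3, size=(8, 30))))
        k = gk.gaussian_kernel(d, 1 - 1e-9)
        np.testing.assert_allclose(k.values, np.ones((8, 8)), atol=1e-6)

    def test_positive_semidefinite_on_random_markers(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            d = gk.squared_distance_matrix(_markers(rng.integers(0, 3, size=(15, 25))))
            for rho in (0.1, 0.5, 0.9):
                w = np.linalg.eigvalsh(gk.gaussian_kernel(d, rho).values)
                assert w.min() >= -1e-8


class TestNTBandwidth:
    def test_value_is_exp_minus_one(self):
        assert gk.nt_rho() == pytest.approx(math.exp(-1.0), abs=0)

    def test_gamma_one_kernel(self):
        d = gk.DistanceMatrix(np.array([[0.0, 0.8], [0.8, 0.0]]), 1.0, ("a", "b"))
        np.testing.assert_allclose(gk.gaussian_kernel(d, gk.nt_rho()).values, np.exp(-d.d2))

    def test_inside_default_grid_range(self):
        grid = gk.make_grid()
        assert grid[0] < gk.nt_rho() < grid[-1]


class TestLinearGRM:
    def test_vanraden_single_marker(self):
        g = gk.linear_grm(_markers([[0], [1], [2]]))
        np.testing.assert_allclose(g.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValidationError, match="monomorphic"):
            gk.linear_grm(_markers([[2, 0], [2, 0], [2, 0]]))

    def test_row_sums_vanish(self):
        rng = np.random.default_rng(1)
        g = gk.linear_grm(_markers(rng.integers(0, 3, size=(10, 50))))
        np.testing.assert_allclose(g.values.sum(axis=1), 0.0, atol=1e-9)


class TestGEKernel:
    def _design(self, lines, envs):
        import pandas as pd

        df = pd.DataFrame({"line": lines, "env": envs, "T1": np.arange(len(lines), dtype=float)})
        return gk.build_design(gk.PhenotypeTable(df, ("T1",)))

    def test_balanced_block_diagonal(self):
        c = 0.4
        k = gk.KernelMatrix(np.array([[1.0, c], [c, 1.0]]), "gaussian", 0.5, ("A", "B"))
        design = self._design(["A", "B", "A", "B"], ["E1", "E1", "E2", "E2"])
        ge = gk.ge_kernel(k, design)
        block = np.array([[1.0, c], [c, 1.0]])
        expected = np.zeros((4, 4))
        expected[:2, :2] = block
        expected[2:, 2:] = block
        np.testing.assert_allclose(ge.values, expected)

    def test_same_line_different_env_is_zero(self):
        k = gk.KernelMatrix(np.eye(2), "gaussian", 0.5, ("A", "B"))
        design = self._design(["A", "B", "A"], ["E1", "E1", "E2"])
        ge = gk.ge_kernel(k, design)
        assert ge.values[0, 2] == 0.0

    def test_identity_kernel_gives_identity(self):
        k = gk.KernelMatrix(np.eye(3), "gaussian", 0.5, ("A", "B", "C"))
        design = self._design(["A", "B", "C", "A"], ["E1", "E1", "E1", "E2"])
        ge = gk.ge_kernel(k, design)
        np.testing.assert_allclose(ge.values, np.eye(4))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(4)
        markers = _markers(rng.integers(0, 3, size=(8, 20)))
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.4)
        lines = [f"L{i}" for i in rng.integers(0, 8, size=30)]
        envs = [f"E{e}" for e in rng.integers(0, 3, size=30)]
        import pandas as pd

        df = pd.DataFrame({"line": lines, "env": envs, "T1": np.ones(30)})
        df = df.drop_duplicates(["line", "env"])
        design = gk.build_design(gk.PhenotypeTable(df, ("T1",)))
        ge = gk.ge_kernel(k, design)
        kpos = {l: i for i, l in enumerate(k.line_ids)}
        n = design.n_obs
        for a in range(n):
            for b in range(n):
                la = kpos[design.line_ids[design.line_idx[a]]]
                lb = kpos[design.line_ids[design.line_idx[b]]]
                want = k.values[la, lb] if design.env_idx[a] == design.env_idx[b] else 0.0
                got = ge.values[a, b] - (gk.kernels.JITTER if a == b and want else 0.0)
                assert got == pytest.approx(want, abs=1e-7)

    def test_dimension_mismatch(self):
        k = gk.KernelMatrix(np.eye(3), "gaussian", 0.5, ("A", "B", "C"))
        design = self._design(["A", "B"], ["E1", "E1"])
        with pytest.raises(ValidationError):
            gk.ge_kernel(k, design)


def test_kernelizer_matches_functional_kernel():
    rng = np.random.default_rng(2)
    codes = rng.integers(0, 3, size=(10, 30))
    markers = _markers(codes)
    ref = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.42).values
    est = GaussianKernelizer(rho=0.42)
    np.testing.assert_allclose(est.fit_transform(codes), ref, atol=1e-12)
    assert est.get_params() == {"rho": 0.42}
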