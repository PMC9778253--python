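import numpy as np
import pandas as pd
import pytest

import gkblup as gk
from gkblup.io import ValidationError
from gkblup.model import MultiTraitGBLUP, PriorSpec, _env_contrasts, fit_gibbs, predict_masked


def _single_trait_table(J, I, y):
    lines = [f"L{i:02d}" for i in range(J)]
    rows = [(l, f"E{e}") for e in range(I) for l in lines]
    df = pd.DataFrame(rows, columns=["line", "env"])
    df["T1"] = y
    return gk.PhenotypeTable(df, ("T1",))


def _mme_blup(pheno, K, sg, se):
    """Henderson's mixed-model equations: the closed-form BLUP oracle."""
    design = gk.build_design(pheno)
    n = pheno.n_obs
    H = _env_contrasts(design.n_envs)
    W = np.ones((n, 1 + H.shape[1]))
    if H.shape[1]:
        W[:, 1:] = H[design.env_idx]
    Z = design.Z_L.astype(float)
    y = pheno.values()[:, 0]
    lam = se / sg
    A = np.block([[W.T @ W, W.T @ Z], [Z.T @ W, Z.T @ Z + lam * np.linalg.inv(K)]])
    sol = np.linalg.solve(A, np.concatenate([W.T @ y, Z.T @ y]))
    return sol[W.shape[1] :]


class TestBLUPReduction:
    def test_matches_henderson_on_random_psd_kernel(self):
        # fixed variances, nT=1: the Gibbs posterior mean of g is the MME BLUP
        rng = np.random.default_rng(42)
        J, I = 12, 2
        y = rng.normal(5.0, 1.0, size=J * I)
        pheno = _single_trait_table(J, I, y)
        X = rng.normal(size=(J, 25))
        K = np.corrcoef(X) * 0.8 + 0.2 * np.eye(J)
        k = gk.KernelMatrix(K, "gaussian", 0.5, tuple(sorted(pheno.line_ids)))
        fit = fit_gibbs(
            pheno,
            k,
            prior=PriorSpec(n_iter=8000, burn_in=1000, thin=1, seed=5),
            include_ge=False,
            fixed_sigma_T=np.array([[1.0]]),
            fixed_R=np.array([[0.5]]),
        )
        g_mme = _mme_blup(pheno, K, 1.0, 0.5)
        assert np.abs(fit.g_hat[:, 0] - g_mme).max() < 0.03

    def test_zero_variance_response(self):
        pheno = _single_trait_table(8, 2, np.full(16, 3.0))
        k = gk.KernelMatrix(np.eye(8), "gaussian", 0.5, tuple(sorted(pheno.line_ids)))
        fit = fit_gibbs(pheno, k, prior=PriorSpec(n_iter=600, burn_in=200, thin=1, seed=1), include_ge=False)
        assert np.abs(fit.g_hat).max() < 0.05
        assert fit.mu_T[0] == pytest.approx(3.0, abs=0.05)


class TestMissingDataAugmentation:
    def test_twin_line_prediction_near_twin(self):
        # duplicate a line's marker vector; with near-zero noise the masked
        # twin cell must be predicted close to its twin's observed value
        rng = np.random.default_rng(8)
        J, p = 20, 60
        codes = rng.integers(0, 3, size=(J, p))
        codes[1] = codes[0]  # L01 is a twin of L00
        markers = gk.MarkerMatrix(tuple(f"L{i:02d}" for i in range(J)), codes)
        cfg = gk.SyntheticConfig(
            J=J, I=2, nT=1, p=p, rho_true=0.5, R_true=np.array([[1e-6]]),
            sigma_T_ge_true=np.array([[1e-6]]), seed=3,
        )
        pheno, truth = gk.simulate_phenotypes(markers, cfg)
        Y = pheno.values()
        twin_rows = np.flatnonzero(pheno.data["line"] == "L01")
        mask = np.zeros_like(Y, dtype=bool)
        mask[twin_rows[0], 0] = True
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        fit = fit_gibbs(
            pheno, k, prior=PriorSpec(n_iter=1200, burn_in=400, thin=1, seed=4), mask=mask
        )
        ref_rows = np.flatnonzero(
            (pheno.data["line"] == "L00") & (pheno.data["env"] == pheno.data["env"][twin_rows[0]])
        )
        assert fit.y_pred[twin_rows[0], 0] == pytest.approx(Y[ref_rows[0], 0], abs=0.35)

    def test_predict_masked_contract(self, tiny_sim):
        markers, pheno, _ = tiny_sim
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        fit = fit_gibbs(pheno, k, prior=PriorSpec(n_iter=200, burn_in=100, thin=1, seed=0))
        assert predict_masked(fit, []).empty
        out = predict_masked(fit, [(0, 0), (1, 1)])
        assert list(out["prediction"]) == [fit.y_pred[0, 0], fit.y_pred[1, 1]]
        with pytest.raises(ValidationError):
            predict_masked(fit, [(10_000, 0)])

    def test_predictions_cover_all_cells(self, tiny_sim):
        markers, pheno, _ = tiny_sim
        Y = pheno.values()
        mask = np.zeros_like(Y, dtype=bool)
        mask[:10, :] = True
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        fit = fit_gibbs(pheno, k, prior=PriorSpec(n_iter=200, burn_in=100, thin=1, seed=0), mask=mask)
        assert np.isfinite(fit.y_pred).all()


class TestPosteriorStructure:
    def test_input_row_order_is_irrelevant(self, tiny_sim):
        markers, pheno, _ = tiny_sim
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        prior = PriorSpec(n_iter=300, burn_in=100, thin=1, seed=9)
        fit1 = fit_gibbs(pheno, k, prior=prior)
        shuffled = gk.PhenotypeTable(
            pheno.data.sample(frac=1.0, random_state=1), pheno.trait_names
        )
        fit2 = fit_gibbs(shuffled, k, prior=prior)
        np.testing.assert_allclose(fit1.g_hat, fit2.g_hat)
        np.testing.assert_allclose(fit1.y_pred, fit2.y_pred)

    def test_identical_seed_identical_output(self, tiny_sim):
        markers, pheno, _ = tiny_sim
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        prior = PriorSpec(n_iter=250, burn_in=100, thin=1, seed=11)
        f1 = fit_gibbs(pheno, k, prior=prior)
        f2 = fit_gibbs(pheno, k, prior=prior)
        np.testing.assert_array_equal(f1.y_pred, f2.y_pred)
        np.testing.assert_array_equal(f1.sigma_T, f2.sigma_T)

    def test_covariance_draws_are_symmetric_pd(self, tiny_sim):
        markers, pheno, _ = tiny_sim
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        fit = fit_gibbs(
            pheno,
            k,
            prior=PriorSpec(n_iter=300, burn_in=100, thin=1, seed=2),
            keep_sigma_draws=True,
        )
        for S in fit.sigma_T_draws:
            np.testing.assert_allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > 0

    def test_sigma_t_interval_coverage(self):
        # 90% posterior intervals for diag(Sigma_T) should cover the
        # generative truth in most replicates (moderate J, reduced chain)
        hits = 0
        total = 0
        for rep in range(12):
            cfg = gk.SyntheticConfig(
                J=120, I=3, nT=2, p=200, rho_true=0.5,
                sigma_T_true=np.array([[1.0, 0.5], [0.5, 1.0]]), seed=500 + rep,
            )
            markers, pheno, truth = gk.simulate(cfg)
            k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
            fit = fit_gibbs(
                pheno,
                k,
                prior=PriorSpec(n_iter=700, burn_in=250, thin=1, seed=rep),
                keep_sigma_draws=True,
            )
            diags = fit.sigma_T_draws[:, [0, 1], [0, 1]]
            lo = np.quantile(diags, 0.05, axis=0)
            hi = np.quantile(diags, 0.95, axis=0)
            for t in range(2):
                total += 1
                hits += int(lo[t] <= truth["sigma_T"][t, t] <= hi[t])
        assert hits / total >= 0.7


class TestValidation:
    def test_prior_spec_guards(self):
        with pytest.raises(ValidationError):
            PriorSpec(n_iter=100, burn_in=200).resolved(2)
        with pytest.raises(ValidationError):
            PriorSpec(thin=0).resolved(2)
        with pytest.raises(ValidationError):
            PriorSpec(iw_df_traits=2).resolved(2)

    def test_all_missing_trait_rejected(self, tiny_sim):
        markers, pheno, _ = tiny_sim
        Y = pheno.values()
        mask = np.zeros_like(Y, dtype=bool)
        mask[:, 0] = True
        k = gk.gaussian_kernel(gk.squared_distance_matrix(markers), 0.5)
        with pytest.raises(ValidationError, match="no observed value"):
            fit_gibbs(pheno, k, prior=PriorSpec(n_iter=20, burn_in=10), mask=mask)


def test_estimator_interface(tiny_sim):
    markers, pheno, _ = tiny_sim
    est = MultiTraitGBLUP(rho=0.5, n_iter=200, burn_in=100, thin=1, seed=1)
    assert est.get_params()["rho"] == 0.5
    est.fit(pheno, markers=markers)
    assert est.sigma_T_.shape == (2, 2)
    assert est.predict().shape == (pheno.n_obs, 2)
    frame = est.predict([(0, 0)])
    assert frame.iloc[0]["prediction"] == est.y_pred_[0, 0]
    est2 = MultiTraitGBLUP(**est.get_params()).set_params(seed=1)
    est2.fit(pheno, markers=markers)
    np.testing.assert_array_equal(est.y_pred_, est2.y_pred_)
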