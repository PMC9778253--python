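"""Bayesian multi-trait kernel GBLUP fitted by Gibbs sampling.

The model, for an n×nT phenotype matrix Y ordered first by environment and
then by line, is

    Y = 1_n μᵀ + X_E β_E + Z_L g + u_gE + ε,

with matrix-variate normal random effects

    g    ~ MN(0, K,     Σ_T)      line main effects (J × nT),
    u_gE ~ MN(0, K_gE,  Σ_TgE)    genotype×environment effects (n × nT),
    ε    ~ MN(0, I_n,   R)        residuals,

where K is a J×J marker kernel (Gaussian or linear GRM) and
K_gE = (Z_E Z_Eᵀ) ⊙ (Z_L K Z_Lᵀ) is its environment-blocked version.  The GE
term is carried at the observation level, which is the only formulation whose
covariance is well defined on unbalanced layouts; its cell-level summary on
the J·I grid is reported after the fit.

Fixed effects use a flat prior; environments are coded with sum-to-zero
contrasts so the intercept μ_T and β_E are jointly identified.  Σ_T, Σ_TgE and
R carry inverse-Wishart priors (default ν = nT + 2, scale I: weakly
informative with a finite prior mean).  Missing phenotype cells — genuinely
missing values as well as cross-validation-masked test cells — are handled by
data augmentation: each sweep draws them from their conditional normal given
the current effects and R, so predictions for masked cells fall out of the
same machinery as the fit itself.

Sampling of each matrix-variate full conditional is decoupled across traits
by the generalized eigendecomposition of its trait covariance against R
(B with Bᵀ R B = I, Bᵀ Σ B = Λ), and across lines by the eigendecomposition
of K; balanced designs reduce every line-effect update to diagonal
arithmetic.  Identical seed and inputs give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.stats import invwishart
from sklearn.base import BaseEstimator, RegressorMixin

from .io import DesignMatrices, PhenotypeTable, ValidationError, build_design, match_lines
from .kernels import KernelMatrix, gaussian_kernel, squared_distance_matrix

_EIG_FLOOR = 1e-12  # relative floor on kernel eigenvalues


@dataclass
class PriorSpec:
    """Prior and sampler settings for :func:`fit_gibbs`.

    Degrees of freedom default to nT + 2 (the smallest value with a finite
    inverse-Wishart mean) and scale matrices to the identity; they are
    resolved once the trait dimension is known.
    """

    iw_df_traits: int | None = None
    iw_scale_traits: np.ndarray | None = None
    iw_df_resid: int | None = None
    iw_scale_resid: np.ndarray | None = None
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0

    def resolved(self, n_traits: int) -> "_ResolvedPrior":
        df_t = self.iw_df_traits if self.iw_df_traits is not None else n_traits + 2
        df_r = self.iw_df_resid if self.iw_df_resid is not None else n_traits + 2
        S_t = (
            np.asarray(self.iw_scale_traits, dtype=float)
            if self.iw_scale_traits is not None
            else np.eye(n_traits)
        )
        S_r = (
            np.asarray(self.iw_scale_resid, dtype=float)
            if self.iw_scale_resid is not None
            else np.eye(n_traits)
        )
        if df_t < n_traits + 2 or df_r < n_traits + 2:
            raise ValidationError("inverse-Wishart df must be at least nT + 2")
        if self.n_iter <= self.burn_in:
            raise ValidationError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        for S in (S_t, S_r):
            if S.shape != (n_traits, n_traits):
                raise ValidationError("prior scale matrix has wrong shape")
        return _ResolvedPrior(df_t, S_t, df_r, S_r, self.n_iter, self.burn_in, self.thin, self.seed)


@dataclass
class _ResolvedPrior:
    df_traits: int
    scale_traits: np.ndarray
    df_resid: int
    scale_resid: np.ndarray
    n_iter: int
    burn_in: int
    thin: int
    seed: int


@dataclass
class PosteriorFit:
    """Posterior summaries of a Gibbs run.

    All effect summaries are posterior means over retained draws.  ``y_pred``
    is the posterior mean of the model's fitted surface (fixed + line + GE
    effects) at every (row, trait) cell, including masked and missing cells.
    ``gE_hat`` is laid out environment-major on the J·I cell grid; cells with
    no observation row keep the prior mean 0.
    """

    mu_T: np.ndarray
    beta_E: np.ndarray
    g_hat: np.ndarray
    gE_hat: np.ndarray
    sigma_T: np.ndarray
    sigma_T_ge: np.ndarray
    R: np.ndarray
    y_pred: np.ndarray
    n_draws: int
    trait_names: tuple[str, ...]
    env_ids: tuple[str, ...]
    line_ids: tuple[str, ...]
    row_env_idx: np.ndarray
    row_line_idx: np.ndarray
    rho: float | None = None
    sigma_T_draws: np.ndarray | None = None  # (n_draws, nT, nT)

    def save(self, outdir: str | Path) -> None:
        """Serialize effects, covariances and predictions to a directory of CSVs
        plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        traits = list(self.trait_names)
        pd.DataFrame([self.mu_T], columns=traits).to_csv(outdir / "mu_T.csv", index=False)
        pd.DataFrame(self.beta_E, index=list(self.env_ids), columns=traits).to_csv(
            outdir / "beta_E.csv"
        )
        pd.DataFrame(self.g_hat, index=list(self.line_ids), columns=traits).to_csv(
            outdir / "g_hat.csv"
        )
        cells = [f"{e}:{l}" for e in self.env_ids for l in self.line_ids]
        pd.DataFrame(self.gE_hat, index=cells, columns=traits).to_csv(outdir / "gE_hat.csv")
        for name, mat in (("sigma_T", self.sigma_T), ("sigma_T_ge", self.sigma_T_ge), ("R", self.R)):
            pd.DataFrame(mat, index=traits, columns=traits).to_csv(outdir / f"{name}.csv")
        pred = pd.DataFrame(self.y_pred, columns=traits)
        pred.insert(0, "env", [self.env_ids[e] for e in self.row_env_idx])
        pred.insert(1, "line", [self.line_ids[l] for l in self.row_line_idx])
        pred.to_csv(outdir / "y_pred.csv", index=False)
        manifest = {"n_draws": int(self.n_draws), "rho": self.rho, "traits": traits}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# internal linear algebra helpers
# ---------------------------------------------------------------------------


def _env_contrasts(I: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: I×(I−1), columns summing to zero."""
    if I == 1:
        return np.zeros((1, 0))
    H = np.zeros((I, I - 1))
    H[: I - 1, :] = np.eye(I - 1)
    H[I - 1, :] = -1.0
    return H


def _clamped_eigh(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh((M + M.T) / 2.0)
    floor = max(d.max(), 1.0) * _EIG_FLOOR
    return np.clip(d, floor, None), U


def _draw_iw(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    scale = (scale + scale.T) / 2.0
    draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
    draw = np.atleast_2d(draw)
    return (draw + draw.T) / 2.0


class _JointLocationSampler:
    """Joint draw of the fixed effects and the line effects per transformed
    trait.

    Sampling Θ and g in one block (rather than one after the other) removes
    the strong posterior correlation between the intercept and the mean of g
    (and between β_E and environment averages of g), which otherwise dominates
    the chain's autocorrelation.  In the trait coordinates defined by the
    generalized eigendecomposition of (Σ_T, R), each transformed trait is an
    independent Gaussian linear model with unit residual variance; the joint
    full conditional of (Θ̃_t, a_t) — a_t the line effects in the kernel's
    eigenbasis — is Gaussian with precision

        [[WᵀW,      Wᵀ Z U          ],
         [Uᵀ Zᵀ W,  Uᵀ ZᵀZ U + (λ_t D)⁻¹]].
    """

    def __init__(self, W: np.ndarray, U: np.ndarray, d: np.ndarray, counts: np.ndarray, line_idx: np.ndarray):
        self.U = U
        self.d = d
        self.kw = W.shape[1]
        J = U.shape[0]
        self.dim = self.kw + J
        ZtW = np.zeros((J, self.kw))
        for c in range(self.kw):
            ZtW[:, c] = np.bincount(line_idx, weights=W[:, c], minlength=J)
        self.WtW = W.T @ W
        self.G1 = U.T @ ZtW  # (J, kw) = (Wᵀ Z U)ᵀ
        self.M = (U * counts[:, None].astype(float)).T @ U  # Uᵀ ZᵀZ U
        self.P_base = np.zeros((self.dim, self.dim))
        self.P_base[: self.kw, : self.kw] = self.WtW
        self.P_base[: self.kw, self.kw :] = self.G1.T
        self.P_base[self.kw :, : self.kw] = self.G1
        self.P_base[self.kw :, self.kw :] = self.M

    def sample(
        self, WtY: np.ndarray, A: np.ndarray, lam: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (Θ̃, g̃): fixed effects and line effects in transformed-trait
        coordinates (g̃ already back in the line basis, U a)."""
        nT = A.shape[1]
        kw, J = self.kw, self.U.shape[0]
        Theta_t = np.empty((kw, nT))
        a = np.empty((J, nT))
        rhs = np.empty(self.dim)
        diag_idx = np.arange(kw, self.dim)
        for t in range(nT):
            P = self.P_base.copy()
            P[diag_idx, diag_idx] += 1.0 / (lam[t] * self.d)
            cF, low = sla.cho_factor(P, lower=True, check_finite=False)
            rhs[:kw] = WtY[:, t]
            rhs[kw:] = A[:, t]
            mean = sla.cho_solve((cF, low), rhs, check_finite=False)
            draw = mean + sla.solve_triangular(
                cF.T, rng.standard_normal(self.dim), lower=False, check_finite=False
            )
            Theta_t[:, t] = draw[:kw]
            a[:, t] = draw[kw:]
        return Theta_t, self.U @ a


# ---------------------------------------------------------------------------
# the fitter
# ---------------------------------------------------------------------------


def fit_gibbs(
    pheno: PhenotypeTable,
    k: KernelMatrix,
    design: DesignMatrices | None = None,
    prior: PriorSpec | None = None,
    include_ge: bool = True,
    *,
    mask: np.ndarray | None = None,
    fixed_sigma_T: np.ndarray | None = None,
    fixed_sigma_T_ge: np.ndarray | None = None,
    fixed_R: np.ndarray | None = None,
    k_eig: tuple[np.ndarray, np.ndarray] | None = None,
    keep_sigma_draws: bool = False,
) -> PosteriorFit:
    """Fit the multi-trait kernel model by Gibbs sampling.

    Parameters
    ----------
    pheno, k, design
        Phenotypes (canonical row order), a line-level kernel covering every
        line of the design, and the design built from the same table (built
        automatically when omitted).
    prior
        :class:`PriorSpec`; defaults are used when omitted.
    include_ge
        Whether to include the genotype×environment term.
    mask
        Optional boolean n×nT array marking cells to treat as unobserved
        (cross-validation test cells).  Masked cells are sampled by data
        augmentation, never dropped.
    fixed_sigma_T, fixed_sigma_T_ge, fixed_R
        Freeze the corresponding covariance at a known value instead of
        sampling it (used for exact-BLUP checks).
    k_eig
        Precomputed eigendecomposition ``(U, d)`` of the kernel restricted to
        the design's line order (an optimization for bandwidth sweeps).
    keep_sigma_draws
        Retain the per-draw Σ_T samples for interval diagnostics.
    """
    if design is None:
        design = build_design(pheno)
    prior = prior or PriorSpec()
    n, nT = pheno.n_obs, pheno.n_traits
    J, I = design.n_lines, design.n_envs
    rp = prior.resolved(nT)
    rng = np.random.default_rng(rp.seed)

    Y_input = pheno.values()
    obs = ~np.isnan(Y_input)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n, nT):
            raise ValidationError(f"mask must have shape {(n, nT)}, got {mask.shape}")
        obs = obs & ~mask
    if not obs.any(axis=0).all():
        bad = [pheno.trait_names[t] for t in range(nT) if not obs[:, t].any()]
        raise ValidationError(f"trait(s) with no observed value: {bad}")

    # kernel restricted to the design's line order
    if k.line_ids is not None and tuple(k.line_ids) != tuple(design.line_ids):
        pos = {l: i for i, l in enumerate(k.line_ids)}
        missing = [l for l in design.line_ids if l not in pos]
        if missing:
            raise ValidationError(f"kernel lacks line(s) {missing[:3]}")
        sel = np.array([pos[l] for l in design.line_ids])
        K = k.values[np.ix_(sel, sel)]
    else:
        if k.values.shape[0] != J:
            raise ValidationError("kernel dimension does not match the design")
        K = k.values

    if k_eig is not None:
        d_K, U_K = np.clip(k_eig[1], max(float(np.max(k_eig[1])), 1.0) * _EIG_FLOOR, None), k_eig[0]
    else:
        d_K, U_K = _clamped_eigh(K)
    if d_K[-1] <= 0:
        raise ValidationError("kernel is not positive semidefinite after jitter")

    line_idx = design.line_idx
    env_idx = design.env_idx
    counts = design.line_counts().astype(float)

    # GE blocks: one per environment; reuse the full eigendecomposition when a
    # block contains every line in kernel order (balanced layouts).
    ge_blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    if include_ge:
        full = np.arange(J)
        for e in range(I):
            rows = np.flatnonzero(env_idx == e)
            lines_e = line_idx[rows]
            if lines_e.size == J and np.array_equal(lines_e, full):
                d_e, U_e = d_K, U_K
            else:
                d_e, U_e = _clamped_eigh(K[np.ix_(lines_e, lines_e)])
            ge_blocks.append((rows, U_e, d_e))

    # fixed-effect design: intercept + sum-to-zero environment contrasts
    H = _env_contrasts(I)
    W = np.ones((n, 1 + H.shape[1]))
    if H.shape[1]:
        W[:, 1:] = H[env_idx, :]
    loc_sampler = _JointLocationSampler(W, U_K, d_K, counts, line_idx)

    # missingness patterns (over the full run: obs is fixed, Y is augmented)
    miss = ~obs
    patterns, pat_inv = np.unique(miss, axis=0, return_inverse=True)

    # --- initialization ---------------------------------------------------
    Y = Y_input.copy()
    col_mean = np.array(
        [np.nanmean(np.where(obs[:, t], Y_input[:, t], np.nan)) for t in range(nT)]
    )
    for t in range(nT):
        Y[~obs[:, t], t] = col_mean[t]
    Theta = np.zeros((W.shape[1], nT))
    Theta[0] = col_mean
    g = np.zeros((J, nT))
    u_ge = np.zeros((n, nT))
    resid_var = np.maximum(np.var(Y - W @ Theta, axis=0), 1e-6)
    Sigma_T = np.diag(resid_var / 2.0) if fixed_sigma_T is None else np.asarray(fixed_sigma_T, float)
    Sigma_ge = (
        np.diag(resid_var / 4.0) if fixed_sigma_T_ge is None else np.asarray(fixed_sigma_T_ge, float)
    )
    R = np.diag(resid_var / 2.0) if fixed_R is None else np.asarray(fixed_R, float)

    # --- accumulators -----------------------------------------------------
    acc = {
        "Theta": np.zeros_like(Theta),
        "g": np.zeros_like(g),
        "u_ge": np.zeros_like(u_ge),
        "Sigma_T": np.zeros((nT, nT)),
        "Sigma_ge": np.zeros((nT, nT)),
        "R": np.zeros((nT, nT)),
        "F": np.zeros((n, nT)),
    }
    sigma_draws: list[np.ndarray] = []
    n_kept = 0

    for it in range(rp.n_iter):
        fitted = W @ Theta + g[line_idx]
        if include_ge:
            fitted = fitted + u_ge

        # (a) data augmentation for missing / masked cells
        for pid in range(patterns.shape[0]):
            m = patterns[pid]
            if not m.any():
                continue
            rows = np.flatnonzero(pat_inv == pid)
            o = ~m
            if not o.any():
                C = R[np.ix_(m, m)]
                Lc = np.linalg.cholesky(C)
                Y[np.ix_(rows, m)] = fitted[np.ix_(rows, m)] + rng.standard_normal(
                    (rows.size, int(m.sum()))
                ) @ Lc.T
            else:
                Roo = R[np.ix_(o, o)]
                Gmat = R[np.ix_(m, o)] @ np.linalg.inv(Roo)
                C = R[np.ix_(m, m)] - Gmat @ R[np.ix_(o, m)]
                Lc = np.linalg.cholesky((C + C.T) / 2.0)
                mean = fitted[np.ix_(rows, m)] + (
                    Y[np.ix_(rows, o)] - fitted[np.ix_(rows, o)]
                ) @ Gmat.T
                Y[np.ix_(rows, m)] = mean + rng.standard_normal((rows.size, int(m.sum()))) @ Lc.T

        # (b)+(c) joint draw of fixed effects and line main effects, per
        # transformed trait (see _JointLocationSampler)
        lam_g, B_g = sla.eigh(Sigma_T, R)
        Y1 = Y - u_ge if include_ge else Y
        Yt = Y1 @ B_g
        WtY = W.T @ Yt
        T1 = np.empty((J, nT))
        for t in range(nT):
            T1[:, t] = np.bincount(line_idx, weights=Yt[:, t], minlength=J)
        Theta_t, g_tilde = loc_sampler.sample(WtY, U_K.T @ T1, lam_g, rng)
        B_inv = np.linalg.inv(B_g)
        Theta = Theta_t @ B_inv
        g = g_tilde @ B_inv

        # (d) genotype×environment effects, blockwise per environment
        if include_ge:
            lam_e, B_e = sla.eigh(Sigma_ge, R)
            Y3 = Y - W @ Theta - g[line_idx]
            Yt = Y3 @ B_e
            u_t = np.empty_like(u_ge)
            for rows, U_b, d_b in ge_blocks:
                A = U_b.T @ Yt[rows]
                a = np.empty_like(A)
                for t in range(nT):
                    prec = 1.0 + 1.0 / (lam_e[t] * d_b)
                    a[:, t] = A[:, t] / prec + rng.standard_normal(d_b.size) / np.sqrt(prec)
                u_t[rows] = U_b @ a
            u_ge = u_t @ np.linalg.inv(B_e)

        # (e) covariance components
        if fixed_sigma_T is None:
            Ag = U_K.T @ g
            S_g = Ag.T @ (Ag / d_K[:, None])
            Sigma_T = _draw_iw(rng, rp.df_traits + J, rp.scale_traits + S_g)
        if include_ge and fixed_sigma_T_ge is None:
            S_ge = np.zeros((nT, nT))
            for rows, U_b, d_b in ge_blocks:
                Au = U_b.T @ u_ge[rows]
                S_ge += Au.T @ (Au / d_b[:, None])
            Sigma_ge = _draw_iw(rng, rp.df_traits + n, rp.scale_traits + S_ge)
        if fixed_R is None:
            fitted = W @ Theta + g[line_idx]
            if include_ge:
                fitted = fitted + u_ge
            E = Y - fitted
            R = _draw_iw(rng, rp.df_resid + n, rp.scale_resid + E.T @ E)

        if it >= rp.burn_in and (it - rp.burn_in) % rp.thin == 0:
            fitted = W @ Theta + g[line_idx]
            if include_ge:
                fitted = fitted + u_ge
            acc["Theta"] += Theta
            acc["g"] += g
            acc["u_ge"] += u_ge
            acc["Sigma_T"] += Sigma_T
            acc["Sigma_ge"] += Sigma_ge
            acc["R"] += R
            acc["F"] += fitted
            if keep_sigma_draws:
                sigma_draws.append(Sigma_T.copy())
            n_kept += 1

    for key in acc:
        acc[key] = acc[key] / n_kept
    mu_T = acc["Theta"][0].copy()
    beta_E = H @ acc["Theta"][1:] if H.shape[1] else np.zeros((I, nT))

    gE_hat = np.zeros((J * I, nT))
    if include_ge:
        gE_hat[env_idx * J + line_idx] = acc["u_ge"]

    return PosteriorFit(
        mu_T=mu_T,
        beta_E=beta_E,
        g_hat=acc["g"],
        gE_hat=gE_hat,
        sigma_T=acc["Sigma_T"],
        sigma_T_ge=acc["Sigma_ge"],
        R=acc["R"],
        y_pred=acc["F"],
        n_draws=n_kept,
        trait_names=pheno.trait_names,
        env_ids=design.env_ids,
        line_ids=design.line_ids,
        row_env_idx=env_idx,
        row_line_idx=line_idx,
        rho=k.param,
        sigma_T_draws=np.array(sigma_draws) if keep_sigma_draws else None,
    )


def predict_masked(fit: PosteriorFit, mask) -> pd.DataFrame:
    """Predictions at a set of (row, trait) cells.

    ``mask`` is either a boolean n×nT array or a sequence of (row, trait)
    index pairs.  Returns a tidy frame with row, line, env, trait and the
    posterior-mean prediction.
    """
    n, nT = fit.y_pred.shape
    if isinstance(mask, np.ndarray) and mask.dtype == bool:
        if mask.shape != (n, nT):
            raise ValidationError(f"mask must have shape {(n, nT)}")
        rows, traits = np.nonzero(mask)
    else:
        pairs = list(mask)
        if not pairs:
            return pd.DataFrame(columns=["row", "line", "env", "trait", "prediction"])
        rows = np.array([p[0] for p in pairs], dtype=int)
        traits = np.array([p[1] for p in pairs], dtype=int)
        if rows.size and (rows.min() < 0 or rows.max() >= n or traits.min() < 0 or traits.max() >= nT):
            raise ValidationError("mask references cells outside the fitted table")
    return pd.DataFrame(
        {
            "row": rows,
            "line": [fit.line_ids[fit.row_line_idx[r]] for r in rows],
            "env": [fit.env_ids[fit.row_env_idx[r]] for r in rows],
            "trait": [fit.trait_names[t] for t in traits],
            "prediction": fit.y_pred[rows, traits],
        }
    )


class MultiTraitGBLUP(RegressorMixin, BaseEstimator):
    """Estimator wrapper around :func:`fit_gibbs`.

    Parameters mirror :class:`PriorSpec` plus the kernel choice.  ``kernel``
    may be a precomputed :class:`~gkblup.kernels.KernelMatrix`; when None, a
    Gaussian kernel with bandwidth ``rho`` is built from the marker matrix
    passed to :meth:`fit`.

    Examples
    --------
    >>> est = MultiTraitGBLUP(rho=0.5, n_iter=500, burn_in=200, seed=1)
    >>> est.fit(pheno, markers=markers)          # doctest: +SKIP
    >>> est.predict(mask)                        # doctest: +SKIP
    """

    def __init__(
        self,
        kernel: KernelMatrix | None = None,
        rho: float | None = None,
        include_ge: bool = True,
        n_iter: int = 3000,
        burn_in: int = 1000,
        thin: int = 2,
        iw_df: int | None = None,
        seed: int = 0,
    ):
        self.kernel = kernel
        self.rho = rho
        self.include_ge = include_ge
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.iw_df = iw_df
        self.seed = seed

    def fit(self, pheno: PhenotypeTable, y=None, *, markers=None, mask=None):
        if self.kernel is not None:
            k = self.kernel
        else:
            if markers is None:
                raise ValidationError("either a precomputed kernel or markers are required")
            import math

            rho = self.rho if self.rho is not None else math.exp(-1.0)
            k = gaussian_kernel(squared_distance_matrix(markers), rho)
            match_lines(pheno, markers)
        prior = PriorSpec(
            iw_df_traits=self.iw_df,
            iw_df_resid=self.iw_df,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
        )
        self.fit_ = fit_gibbs(pheno, k, prior=prior, include_ge=self.include_ge, mask=mask)
        self.mu_T_ = self.fit_.mu_T
        self.beta_E_ = self.fit_.beta_E
        self.g_hat_ = self.fit_.g_hat
        self.gE_hat_ = self.fit_.gE_hat
        self.sigma_T_ = self.fit_.sigma_T
        self.sigma_T_ge_ = self.fit_.sigma_T_ge
        self.R_ = self.fit_.R
        self.y_pred_ = self.fit_.y_pred
        self.n_draws_ = self.fit_.n_draws
        return self

    def predict(self, mask=None) -> np.ndarray | pd.DataFrame:
        """Posterior-mean predictions: the full n×nT surface, or the cells of
        ``mask`` as a tidy frame."""
        if not hasattr(self, "fit_"):
            raise ValidationError("estimator is not fitted")
        if mask is None:
            return self.y_pred_
        return predict_masked(self.fit_, mask)
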