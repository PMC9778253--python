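"""Synthetic marker and phenotype data drawn from the generative model.

The generator samples markers (allele frequencies uniform in a MAF band,
binomial genotype codes), builds the true Gaussian kernel at a known
bandwidth ρ_true, draws line effects g ~ MN(0, K, Σ_T), per-environment GE
effects ~ MN(0, K, Σ_TgE), residuals ~ MN(0, I, R), and assembles the
phenotype table exactly as the model assumes.  The truth record (every draw
and parameter) is returned so recovery studies can compare posterior against
generative values.

Presets reproduce the shapes of five published breeding datasets — lines,
environments, traits, marker counts and line×environment balance — not their
linkage structure, trait means or genetic architectures:

========== ====  ==  ==  ======  ==============================
preset        J   I  nT       p  layout
japonica    320   5   4   44598  per-year line counts 93/292/316/316/134
indica      327   3   4   92430  balanced (981 observations)
groundnut   318   4   4    8268  balanced (1272 observations)
cotton      859   7   2    5000  each line in exactly one environment
disease     438   6   3   11617  balanced (2628 observations), 0/1 markers
========== ====  ==  ==  ======  ==============================

Residual scale is controlled through ``signal_fraction``: after the genetic
terms are realized, per-trait residual variances are set so the genetic share
of phenotypic variance is approximately that fraction (0.6 by default, a
moderately heritable trait); an explicit ``R_true`` overrides this.
Unbalancedness removes whole line×environment cells, never individual traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cv import derive_seed
from .io import MarkerMatrix, PhenotypeTable, ValidationError
from .kernels import gaussian_kernel, squared_distance_matrix


@dataclass
class SyntheticConfig:
    J: int = 150
    I: int = 3
    nT: int = 2
    p: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho_true: float = 0.5
    sigma_T_true: Optional[np.ndarray] = None  # default: unit diagonal, 0.5 correlation
    sigma_T_ge_true: Optional[np.ndarray] = None  # default: 0.5 × Σ_T
    R_true: Optional[np.ndarray] = None  # default: derived from signal_fraction
    beta_E_true: Optional[np.ndarray] = None  # default: seeded N(0, 0.5²) draws
    mu_true: Optional[np.ndarray] = None  # default: 10 per trait
    missing_fraction: float = 0.0
    signal_fraction: float = 0.6
    marker_ploidy: int = 2  # 1 for presence/absence panels
    env_line_counts: Optional[tuple[int, ...]] = None
    one_env_per_line: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range bounds must lie in (0, 0.5]")
        if not (0.0 < self.rho_true < 1.0):
            raise ValidationError("rho_true must lie in (0, 1)")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValidationError("missing_fraction must lie in [0, 1)")
        if not (0.0 < self.signal_fraction < 1.0):
            raise ValidationError("signal_fraction must lie in (0, 1)")
        if self.env_line_counts is not None and len(self.env_line_counts) != self.I:
            raise ValidationError("env_line_counts must have one entry per environment")

    # -- resolved parameter matrices --------------------------------------
    def sigma_T(self) -> np.ndarray:
        if self.sigma_T_true is not None:
            return _check_pd(np.asarray(self.sigma_T_true, float), "sigma_T_true")
        S = np.full((self.nT, self.nT), 0.5)
        np.fill_diagonal(S, 1.0)
        return S

    def sigma_T_ge(self) -> np.ndarray:
        if self.sigma_T_ge_true is not None:
            return _check_pd(np.asarray(self.sigma_T_ge_true, float), "sigma_T_ge_true")
        return 0.5 * self.sigma_T()

    def mu(self) -> np.ndarray:
        if self.mu_true is not None:
            return np.asarray(self.mu_true, float)
        return np.full(self.nT, 10.0)


def _check_pd(S: np.ndarray, name: str) -> np.ndarray:
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"{name} is not positive definite") from exc
    return S


def simulate_markers(cfg: SyntheticConfig) -> MarkerMatrix:
    """Draw a J×p marker panel: f_j ~ U(maf_range), codes ~ Binomial(ploidy, f_j);
    monomorphic columns are resampled.  Deterministic given the seed."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "markers"))
    lo, hi = cfg.maf_range
    codes = np.empty((cfg.J, cfg.p), dtype=np.int64)
    todo = np.arange(cfg.p)
    while todo.size:
        f = rng.uniform(lo, hi, size=todo.size)
        codes[:, todo] = rng.binomial(cfg.marker_ploidy, f, size=(cfg.J, todo.size))
        mono = (codes[:, todo] == codes[0, todo]).all(axis=0)
        todo = todo[mono]
    width = len(str(cfg.J))
    ids = tuple(f"L{i + 1:0{width}d}" for i in range(cfg.J))
    return MarkerMatrix(ids, codes)


def simulate_phenotypes(
    markers: MarkerMatrix, cfg: SyntheticConfig
) -> tuple[PhenotypeTable, dict]:
    """Draw phenotypes from the generative model on top of a marker panel.

    Returns the phenotype table (canonical order, unbalancedness applied) and
    the truth record with every generative draw and parameter.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "phenotypes"))
    J, I, nT = markers.n_lines, cfg.I, cfg.nT
    dist = squared_distance_matrix(markers)
    K = gaussian_kernel(dist, cfg.rho_true).values
    L_K = np.linalg.cholesky(K + 1e-8 * np.eye(J))

    Sigma_T = cfg.sigma_T()
    Sigma_ge = cfg.sigma_T_ge()
    mu = cfg.mu()
    L_T = np.linalg.cholesky(Sigma_T)
    L_ge = np.linalg.cholesky(Sigma_ge)
    beta_E = (
        np.asarray(cfg.beta_E_true, float)
        if cfg.beta_E_true is not None
        else rng.normal(0.0, 0.5, size=(I, nT))
    )
    if beta_E.shape != (I, nT):
        raise ValidationError(f"beta_E_true must be {I}×{nT}")

    g = L_K @ rng.standard_normal((J, nT)) @ L_T.T
    gE = np.stack([L_K @ rng.standard_normal((J, nT)) @ L_ge.T for _ in range(I)])

    line_order = tuple(sorted(markers.line_ids))
    lpos = {l: i for i, l in enumerate(markers.line_ids)}
    perm = np.array([lpos[l] for l in line_order])
    env_ids = tuple(f"E{e + 1}" for e in range(I))

    # full factorial in canonical (env, line) order
    env_idx = np.repeat(np.arange(I), J)
    line_idx = np.tile(perm, I)  # marker-order index of each row's line
    genetic = g[line_idx] + gE[env_idx, line_idx]
    var_gen = genetic.var(axis=0)

    if cfg.R_true is not None:
        R = _check_pd(np.asarray(cfg.R_true, float), "R_true")
    else:
        sf = cfg.signal_fraction
        R = np.diag(np.maximum(var_gen, 1e-12) * (1.0 - sf) / sf)
    eps = rng.standard_normal((I * J, nT)) @ np.linalg.cholesky(R).T
    Y = mu + beta_E[env_idx] + genetic + eps

    keep = _layout_mask(cfg, rng, I, J)
    realized_signal = var_gen / (var_gen + np.diag(R))

    df = pd.DataFrame(
        {
            "line": np.tile(np.array(line_order), I)[keep],
            "env": np.repeat(np.array(env_ids), J)[keep],
        }
    )
    trait_names = tuple(f"T{t + 1}" for t in range(nT))
    for t, name in enumerate(trait_names):
        df[name] = Y[keep, t]
    pheno = PhenotypeTable(df, trait_names)

    truth = {
        "mu": mu,
        "beta_E": beta_E,
        "g": g,
        "gE": gE,
        "eps": eps,
        "sigma_T": Sigma_T,
        "sigma_T_ge": Sigma_ge,
        "R": R,
        "rho_true": cfg.rho_true,
        "K": K,
        "scale_factor": dist.scale_factor,
        "line_ids": markers.line_ids,
        "env_ids": env_ids,
        "keep_mask": keep,
        "realized_signal_fraction": realized_signal,
    }
    return pheno, truth


def _layout_mask(cfg: SyntheticConfig, rng: np.random.Generator, I: int, J: int) -> np.ndarray:
    """Which full-factorial (env, line) cells survive, per the layout rules."""
    keep = np.ones(I * J, dtype=bool)
    if cfg.one_env_per_line:
        keep[:] = False
        env_of_line = rng.integers(0, I, size=J)
        keep[env_of_line * J + np.arange(J)] = True
    elif cfg.env_line_counts is not None:
        keep[:] = False
        for e, count in enumerate(cfg.env_line_counts):
            if not (0 < count <= J):
                raise ValidationError(f"env_line_counts[{e}]={count} outside 1..{J}")
            chosen = rng.choice(J, size=count, replace=False)
            keep[e * J + chosen] = True
    elif cfg.missing_fraction > 0.0:
        keep = rng.uniform(size=I * J) >= cfg.missing_fraction
        # every line must keep at least one cell (lines are the prediction unit)
        for l in range(J):
            cells = l + J * np.arange(I)
            if not keep[cells].any():
                keep[rng.choice(cells)] = True
        # and every environment at least one row
        for e in range(I):
            cells = e * J + np.arange(J)
            if not keep[cells].any():
                keep[rng.choice(cells)] = True
    return keep


_PRESETS: dict[str, dict] = {
    "japonica": dict(J=320, I=5, nT=4, p=44598, env_line_counts=(93, 292, 316, 316, 134)),
    "indica": dict(J=327, I=3, nT=4, p=92430),
    "groundnut": dict(J=318, I=4, nT=4, p=8268),
    "cotton": dict(J=859, I=7, nT=2, p=5000, one_env_per_line=True),
    "disease": dict(J=438, I=6, nT=3, p=11617, marker_ploidy=1),
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """A :class:`SyntheticConfig` with a named dataset shape.

    Overrides (e.g. a smaller ``p`` for quick studies) are applied on top of
    the preset shape.
    """
    if name not in _PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SyntheticConfig(seed=seed, **kwargs)


def simulate(cfg: SyntheticConfig) -> tuple[MarkerMatrix, PhenotypeTable, dict]:
    """Markers + phenotypes + truth in one call."""
    markers = simulate_markers(cfg)
    pheno, truth = simulate_phenotypes(markers, cfg)
    return markers, pheno, truth
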