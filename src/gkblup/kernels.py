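"""Marker-based kernels: Gaussian (bandwidth-parameterized), linear GRM, and
the genotype×environment kernel.

The Gaussian kernel is K(x_i, x_j) = exp(−γ‖x_i − x_j‖²), reparameterized as
ρ^{‖x_i − x_j‖²} with ρ = e^(−γ) ∈ (0, 1) so the bandwidth lives on the unit
interval.  Squared distances are scaled by their maximum, so d² ∈ [0, 1] and
K = ρ^{d²} spans (ρ, 1]: every bandwidth in (0, 1) then produces a
non-degenerate kernel, and γ = 1 (ρ = e⁻¹) is a sensible untuned default.
The scale factor is recorded for reproducibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DesignMatrices, MarkerMatrix, ValidationError

logger = logging.getLogger(__name__)

#: jitter added to a kernel diagonal when its smallest eigenvalue falls below
#: PSD_TOL (numerical rescue only; the Gaussian kernel is PSD by construction)
JITTER = 1e-8
PSD_TOL = 1e-10


class DegenerateDistanceError(ValidationError):
    """All lines have identical marker vectors: the kernel would be all ones
    regardless of the bandwidth."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Scaled squared Euclidean distances between marker rows.

    ``d2`` is symmetric with zero diagonal and entries in [0, 1];
    ``scale_factor`` is the raw maximum squared distance that was divided out.
    """

    d2: np.ndarray
    scale_factor: float
    line_ids: tuple[str, ...]


@dataclass(frozen=True)
class KernelMatrix:
    """A symmetric similarity matrix among lines (or observation rows).

    ``kind`` is ``"gaussian"``, ``"linear"`` or ``"ge"``; ``param`` carries the
    bandwidth ρ for Gaussian kernels and is None otherwise.  ``line_ids`` label
    rows for line-level kernels; the observation-level GE kernel has none.
    """

    values: np.ndarray
    kind: str
    param: float | None = None
    line_ids: tuple[str, ...] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _ensure_psd(values: np.ndarray, what: str) -> np.ndarray:
    """Add JITTER to the diagonal if the minimum eigenvalue is below PSD_TOL."""
    w = np.linalg.eigvalsh(values)
    if w[0] < PSD_TOL:
        logger.info("adding %.0e jitter to %s (min eig %.3e)", JITTER, what, w[0])
        values = values + JITTER * np.eye(values.shape[0])
    return values


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def squared_distance_matrix(markers: MarkerMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distances between lines, scaled to [0, 1].

    Raises :class:`DegenerateDistanceError` when all lines are identical.
    """
    raw = pdist(markers.codes.astype(float), metric="sqeuclidean")
    scale = float(raw.max()) if raw.size else 0.0
    if scale <= 0.0:
        raise DegenerateDistanceError(
            "all lines have identical marker vectors; distances are all zero"
        )
    d2 = squareform(raw / scale)
    return DistanceMatrix(d2=d2, scale_factor=scale, line_ids=markers.line_ids)


def gaussian_kernel(d: DistanceMatrix, rho: float) -> KernelMatrix:
    """Gaussian kernel ρ^{d²} = exp(−γ d²) with γ = −log ρ, ρ ∈ (0, 1)."""
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie strictly in (0, 1), got {rho}")
    values = np.exp(math.log(rho) * d.d2)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(values=values, kind="gaussian", param=float(rho), line_ids=d.line_ids)


def nt_rho() -> float:
    """The untuned bandwidth: γ = 1, i.e. ρ = e⁻¹."""
    return math.exp(-1.0)


def linear_grm(markers: MarkerMatrix) -> KernelMatrix:
    """VanRaden genomic relationship matrix from 0/1/2 codes.

    Columns are centered at twice the observed allele frequency and the cross
    product is scaled by 2 Σ f_j (1 − f_j).
    """
    codes = markers.codes.astype(float)
    f = codes.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(f * (1.0 - f)))
    if denom <= 0.0:
        raise ValidationError("all markers are monomorphic; GRM denominator is zero")
    W = codes - 2.0 * f
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return KernelMatrix(values=G, kind="linear", param=None, line_ids=markers.line_ids)


def ge_kernel(k: KernelMatrix, design: DesignMatrices) -> KernelMatrix:
    """Genotype×environment kernel (Z_E Z_Eᵀ) ⊙ (Z_L K Z_Lᵀ) at observation level.

    Entry (a, b) equals K[line_a, line_b] when rows a and b share an
    environment, else 0 — block-diagonal per environment under the canonical
    (env, line) row order.
    """
    if k.values.shape[0] != design.n_lines:
        raise ValidationError(
            f"kernel covers {k.values.shape[0]} lines but the design has {design.n_lines}"
        )
    same_env = design.env_idx[:, None] == design.env_idx[None, :]
    values = k.values[np.ix_(design.line_idx, design.line_idx)] * same_env
    # PSD check blockwise: the kernel is block-diagonal per environment, so the
    # global spectrum is the union of the block spectra.
    min_eig = np.inf
    for e in range(design.n_envs):
        rows = np.flatnonzero(design.env_idx == e)
        if rows.size:
            w = np.linalg.eigvalsh(values[np.ix_(rows, rows)])
            min_eig = min(min_eig, w[0])
    if min_eig < PSD_TOL:
        logger.info("adding %.0e jitter to GE kernel (min eig %.3e)", JITTER, min_eig)
        values = values + JITTER * np.eye(values.shape[0])
    return KernelMatrix(values=values, kind="ge", param=k.param, line_ids=None)


def kernel_to_csv(k: KernelMatrix, path) -> None:
    """Export a line-level kernel as a square CSV with line-id headers."""
    import pandas as pd

    ids = list(k.line_ids) if k.line_ids is not None else list(range(k.n))
    pd.DataFrame(k.values, index=ids, columns=ids).to_csv(path)


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------


class GaussianKernelizer(TransformerMixin, BaseEstimator):
    """Transformer mapping marker codes to Gaussian-kernel similarities.

    ``fit`` records the reference lines and the distance scale (maximum raw
    squared distance among them); ``transform(X)`` returns the kernel between
    the rows of X and the reference lines, so ``fit_transform`` on the training
    panel yields the square training kernel.

    Parameters
    ----------
    rho : float, default e⁻¹
        Bandwidth on the reparameterized scale, strictly inside (0, 1).
    """

    def __init__(self, rho: float = math.exp(-1.0)):
        self.rho = rho

    def fit(self, X, y=None):
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie strictly in (0, 1), got {self.rho}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D array with at least two rows")
        raw = pdist(X, metric="sqeuclidean")
        scale = float(raw.max())
        if scale <= 0.0:
            raise DegenerateDistanceError("all rows identical; zero distance scale")
        self.X_fit_ = X
        self.scale_factor_ = scale
        return self

    def transform(self, X):
        from scipy.spatial.distance import cdist

        X = np.asarray(X, dtype=float)
        d2 = cdist(X, self.X_fit_, metric="sqeuclidean") / self.scale_factor_
        return np.exp(math.log(self.rho) * d2)
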