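"""Bandwidth-selection strategies over ρ ∈ (0, 1).

Three strategies share one objective — the inner-cross-validation mean NRMSE:

* NT   — no tuning: γ = 1, i.e. ρ = e⁻¹, no inner fitting;
* GrS  — grid search over 26 values spanning 0.01–0.999 (step 0.04 plus the
         0.999 endpoint);
* BO   — Bayesian optimization with a Gaussian-process surrogate (Matérn-5/2,
         constant mean) and expected-improvement acquisition on a fine lattice.

Ties in the observed objective are broken toward the smallest ρ.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


@dataclass
class TuneResult:
    strategy: str  # NT | GrS | BO
    evaluations: list[tuple[float, float]]
    rho_opt: float
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "strategy": self.strategy,
            "evaluations": [[float(r), float(v)] for r, v in self.evaluations],
            "rho_opt": float(self.rho_opt),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def make_grid(start: float = 0.01, stop: float = 0.999, step: float = 0.04) -> np.ndarray:
    """Arithmetic ρ grid start, start+step, … with the endpoint appended.

    The defaults give the 25 values 0.01, 0.05, …, 0.97 plus 0.999 — 26 grid
    points in total.
    """
    if not (0.0 < start < stop < 1.0):
        raise ValueError(f"need 0 < start < stop < 1, got ({start}, {stop})")
    if step <= 0.0:
        raise ValueError("step must be positive")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    values = start + step * np.arange(n)
    values = values[values <= stop + 1e-12]
    if abs(values[-1] - stop) > 1e-12:
        values = np.append(values, stop)
    return values


def _argmin_smallest_rho(rhos: Sequence[float], vals: Sequence[float]) -> float:
    """Minimizer of the recorded objective; ties go to the smallest ρ."""
    order = np.lexsort((np.asarray(rhos, float),))
    rhos = np.asarray(rhos, float)[order]
    vals = np.asarray(vals, float)[order]
    return float(rhos[int(np.argmin(vals))])


def tune_grid(objective: Callable[[float], float], grid: Sequence[float]) -> TuneResult:
    """Exhaustive evaluation of the objective over the grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid is empty")
    evals = [(float(r), float(objective(float(r)))) for r in grid]
    rho_opt = _argmin_smallest_rho([e[0] for e in evals], [e[1] for e in evals])
    return TuneResult(strategy="GrS", evaluations=evals, rho_opt=rho_opt)


def nt_result() -> TuneResult:
    """The no-tuning 'result': a single untouched evaluation at ρ = e⁻¹."""
    return TuneResult(strategy="NT", evaluations=[(math.exp(-1.0), float("nan"))], rho_opt=math.exp(-1.0))


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    imp = best - mu
    z = imp / sd
    return imp * norm.cdf(z) + sd * norm.pdf(z)


def tune_bo(
    objective: Callable[[float], float],
    bounds: tuple[float, float] = (0.001, 0.999),
    n_init: int = 6,
    n_iter: int = 14,
    seed: int = 0,
) -> TuneResult:
    """Bayesian optimization of the inner objective.

    A GP surrogate (Matérn-5/2 covariance, constant mean, noise 1e−6 on the
    standardized scale — the objective is deterministic given its seeds) is
    fitted to the evaluations so far; expected improvement is maximized over a
    fine candidate lattice.  Starts from ``n_init`` stratified jittered points,
    then performs ``n_iter`` acquisitions.  Deterministic given the seed.
    """
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0) or lo <= 0.0 or hi >= 1.0:
        raise ValueError(f"bounds must lie strictly inside (0, 1), got {bounds}")
    if n_init < 2:
        raise ValueError("need at least two initial evaluations")
    rng = np.random.default_rng(seed)

    edges = np.linspace(lo, hi, n_init + 1)
    x = edges[:-1] + rng.uniform(size=n_init) * (edges[1] - edges[0])
    x = list(np.clip(x, lo, hi))
    y = []
    for xi in x:
        v = float(objective(float(xi)))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value at rho={xi}")
        y.append(v)

    candidates = np.linspace(lo, hi, 997)
    kernel = ConstantKernel(1.0, (1e-6, 1e6)) * Matern(
        length_scale=0.2, length_scale_bounds=(1e-2, 1e1), nu=2.5
    )
    for _ in range(n_iter):
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(seed) % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.asarray(x)[:, None], np.asarray(y))
        mu, sd = gp.predict(candidates[:, None], return_std=True)
        ei = _expected_improvement(mu, sd, min(y))
        # never re-evaluate an (almost) visited point
        dist = np.min(np.abs(candidates[:, None] - np.asarray(x)[None, :]), axis=1)
        ei[dist < 5e-4] = -np.inf
        pick = candidates[int(np.argmax(ei))] if np.isfinite(ei).any() else float(
            rng.uniform(lo, hi)
        )
        v = float(objective(float(pick)))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value at rho={pick}")
        x.append(float(pick))
        y.append(v)

    rho_opt = _argmin_smallest_rho(x, y)
    return TuneResult(strategy="BO", evaluations=list(zip(x, y)), rho_opt=rho_opt, seed=seed)
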