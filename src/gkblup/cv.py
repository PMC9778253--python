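"""Nested cross-validation engine: 7 outer folds for generalization, 5 inner
folds (within each outer-training set) for bandwidth selection.

Folds partition observation rows, stratified by environment so each
environment's rows spread as evenly as possible across folds (a line may then
be in training in one environment and in test in another — the "tested lines
in tested environments" reading).  A ``by_line`` switch partitions lines
instead.  One :class:`FoldPlan` is shared across tuning strategies so
relative-efficiency comparisons are paired.

Per outer fold the engine selects ρ on the inner folds (NT skips selection),
refits on the full outer-training set with the outer-test cells masked —
masked, never dropped, so the test rows' line/environment structure informs
the conditional — and records per-trait per-environment NRMSE on the test
cells.  All sampler seeds derive from one master seed through named
substreams; inner-fold sampler seeds are deliberately shared across candidate
ρ values (common random numbers) so the inner objective is a smooth function
of the bandwidth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    DesignMatrices,
    MarkerMatrix,
    PhenotypeTable,
    ValidationError,
    build_design,
    match_lines,
)
from .kernels import DistanceMatrix, gaussian_kernel, squared_distance_matrix
from .metrics import nrmse, per_fold_rows
from .model import PriorSpec, fit_gibbs
from .tuning import TuneResult, make_grid, nt_result, tune_bo, tune_grid

STRATEGIES = ("NT", "GrS", "BO")


class StratificationError(ValidationError):
    """A stratum has fewer rows than the number of folds."""


def derive_seed(master: int, *parts) -> int:
    """Deterministic child seed (< 2^31) from a master seed and a tag path."""
    tags = [zlib.crc32(str(p).encode()) % (2**31) for p in parts]
    ss = np.random.SeedSequence([int(master) % (2**31), *tags])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FoldPlan:
    """Outer/inner fold assignments over observation rows.

    ``outer[i]`` ∈ {1..k_outer}; ``inner[f][i]`` ∈ {1..k_inner} for rows in
    the outer-training set of fold f and 0 for rows of fold f itself.
    """

    outer: np.ndarray
    inner: dict[int, np.ndarray]
    seed: int

    @property
    def k_outer(self) -> int:
        return int(self.outer.max())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"row": np.arange(len(self.outer)), "outer_fold": self.outer})
        for f in sorted(self.inner):
            df[f"inner_fold_{f}"] = self.inner[f]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "FoldPlan":
        df = pd.read_csv(path)
        outer = df["outer_fold"].to_numpy(dtype=int)
        inner = {
            int(c.split("_")[-1]): df[c].to_numpy(dtype=int)
            for c in df.columns
            if c.startswith("inner_fold_")
        }
        return cls(outer=outer, inner=inner, seed=seed)


def _stratified_folds(strata: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each row a fold in {1..k}, sizes within each stratum differing
    by at most one."""
    out = np.zeros(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < k:
            raise StratificationError(
                f"stratum {s!r} has {len(idx)} rows but {k} folds were requested; "
                "reduce the fold count or switch to by_line folding"
            )
        idx = rng.permutation(idx)
        fold_order = rng.permutation(k) + 1  # rotate which folds get the larger chunks
        for chunk, f in zip(np.array_split(idx, k), fold_order):
            out[chunk] = f
    return out


def make_fold_plan(
    pheno: PhenotypeTable,
    k_outer: int = 7,
    k_inner: int = 5,
    seed: int = 0,
    unit: str = "by_observation",
) -> FoldPlan:
    """Random nested fold plan, stratified by environment, deterministic given
    the seed.

    ``unit="by_line"`` partitions lines instead of observations: all rows of a
    line share its fold (whole-line holdout).
    """
    n = pheno.n_obs
    if n < k_outer:
        raise StratificationError(f"{n} rows cannot be split into {k_outer} folds")
    env = pheno.data["env"].to_numpy()
    rng = np.random.default_rng(derive_seed(seed, "outer"))
    if unit == "by_observation":
        outer = _stratified_folds(env, k_outer, rng)
    elif unit == "by_line":
        lines = pheno.data["line"].to_numpy()
        uniq = np.sort(np.unique(lines))
        if len(uniq) < k_outer:
            raise StratificationError(f"{len(uniq)} lines cannot fill {k_outer} folds")
        line_fold = _stratified_folds(np.zeros(len(uniq)), k_outer, rng)
        lut = dict(zip(uniq, line_fold))
        outer = np.array([lut[l] for l in lines])
    else:
        raise ValidationError(f"unknown fold unit {unit!r}")

    inner: dict[int, np.ndarray] = {}
    for f in range(1, k_outer + 1):
        rng_f = np.random.default_rng(derive_seed(seed, "inner", f))
        train = np.flatnonzero(outer != f)
        assign = np.zeros(n, dtype=int)
        if unit == "by_observation":
            assign[train] = _stratified_folds(env[train], k_inner, rng_f)
        else:
            lines = pheno.data["line"].to_numpy()
            uniq = np.sort(np.unique(lines[train]))
            lf = _stratified_folds(np.zeros(len(uniq)), k_inner, rng_f)
            lut = dict(zip(uniq, lf))
            assign[train] = [lut[l] for l in lines[train]]
        inner[f] = assign
    return FoldPlan(outer=outer, inner=inner, seed=seed)


@dataclass
class CVSettings:
    """Knobs of a nested-CV run (defaults mirror the evaluation protocol:
    7×5 folds come from the plan; 26-point grid; 6+14 BO budget)."""

    grid_start: float = 0.01
    grid_stop: float = 0.999
    grid_step: float = 0.04
    bo_bounds: tuple[float, float] = (0.001, 0.999)
    bo_n_init: int = 6
    bo_n_iter: int = 14
    include_ge: bool = True
    global_mode: str = "pooled"  # or mean_of_env
    dataset_name: str = "synthetic"
    # reduced sampler settings for the (many) inner fits
    tune_n_iter: int = 600
    tune_burn_in: int = 200
    tune_thin: int = 2


@dataclass
class StrategyRun:
    """Everything a strategy run produced: per-fold metric rows, the raw
    outer-test prediction log, tuning traces per fold, and the inner-fold
    prediction log (the audit trail for leakage checks)."""

    strategy: str
    metrics: pd.DataFrame
    predictions: pd.DataFrame
    tune_results: dict[int, TuneResult]
    inner_log: pd.DataFrame


class _KernelCache:
    """Per-run cache of Gaussian kernels and their eigendecompositions keyed
    by ρ (shared across folds — the kernel does not depend on the fold)."""

    def __init__(self, dist: DistanceMatrix):
        self.dist = dist
        self._store: dict[float, tuple] = {}

    def get(self, rho: float):
        key = round(float(rho), 12)
        if key not in self._store:
            k = gaussian_kernel(self.dist, rho)
            d, U = np.linalg.eigh(k.values)
            self._store[key] = (k, (U, d))
        return self._store[key]


class InnerObjective:
    """Mean inner-validation NRMSE as a function of ρ for one outer fold.

    For each inner fold the model is fitted on the outer-training rows with
    the validation cells masked; per-trait NRMSE on the validation cells is
    averaged over traits, then over the inner folds.  Evaluations are logged
    (cell-level) so the selection is auditable after the fact.
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        cache: _KernelCache,
        design_all: DesignMatrices,
        train_rows: np.ndarray,
        inner_assign: np.ndarray,
        prior: PriorSpec,
        settings: CVSettings,
        fold: int,
    ):
        self.cache = cache
        self.settings = settings
        self.prior = prior
        self.fold = fold
        self.log_rows: list[tuple] = []
        self.trait_names = pheno.trait_names
        self.sub = pheno.subset(train_rows)
        self.sub_design = build_design(
            self.sub, line_ids=design_all.line_ids, env_ids=design_all.env_ids
        )
        sub_assign = inner_assign[np.sort(np.asarray(train_rows))]
        self.k_inner = int(sub_assign.max())
        self.val_masks = []
        Y = self.sub.values()
        for j in range(1, self.k_inner + 1):
            rows_j = sub_assign == j
            mask = np.zeros_like(Y, dtype=bool)
            mask[rows_j, :] = True
            self.val_masks.append((j, rows_j, mask & ~np.isnan(Y)))

    def __call__(self, rho: float) -> float:
        k, keig = self.cache.get(rho)
        Y = self.sub.values()
        fold_vals = []
        for j, rows_j, val_cells in self.val_masks:
            prior_j = replace(
                self.prior,
                n_iter=self.settings.tune_n_iter,
                burn_in=self.settings.tune_burn_in,
                thin=self.settings.tune_thin,
                seed=derive_seed(self.prior.seed, "inner", self.fold, j),
            )
            mask = np.zeros_like(Y, dtype=bool)
            mask[rows_j, :] = True
            fit = fit_gibbs(
                self.sub,
                k,
                self.sub_design,
                prior=prior_j,
                include_ge=self.settings.include_ge,
                mask=mask,
                k_eig=keig,
            )
            trait_vals = []
            for t, trait in enumerate(self.trait_names):
                cells = np.flatnonzero(val_cells[:, t])
                if cells.size == 0:
                    continue
                obs = Y[cells, t]
                pred = fit.y_pred[cells, t]
                trait_vals.append(nrmse(obs, pred))
                for r, o, p in zip(cells, obs, pred):
                    self.log_rows.append((self.fold, float(rho), j, int(r), trait, o, p))
            if trait_vals:
                fold_vals.append(float(np.mean(trait_vals)))
        return float(np.mean(fold_vals))

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log_rows,
            columns=["fold", "rho", "inner_fold", "row", "trait", "observed", "predicted"],
        )


def inner_objective(
    rho: float,
    outer_train: PhenotypeTable,
    inner_assign: np.ndarray,
    markers: MarkerMatrix,
    prior: PriorSpec | None = None,
    settings: CVSettings | None = None,
    fold: int = 1,
) -> float:
    """One-shot inner-CV objective evaluation (convenience wrapper around
    :class:`InnerObjective` for a standalone outer-training table)."""
    prior = prior or PriorSpec()
    settings = settings or CVSettings()
    pos = match_lines(outer_train, markers)
    sub_markers = MarkerMatrix(outer_train.line_ids, markers.codes[pos])
    cache = _KernelCache(squared_distance_matrix(sub_markers))
    design = build_design(outer_train)
    obj = InnerObjective(
        outer_train,
        cache,
        design,
        np.arange(outer_train.n_obs),
        np.asarray(inner_assign),
        prior,
        settings,
        fold,
    )
    return obj(rho)


def run_strategy(
    pheno: PhenotypeTable,
    markers: MarkerMatrix,
    strategy: str,
    plan: FoldPlan,
    prior: PriorSpec | None = None,
    settings: CVSettings | None = None,
    outer_folds: Sequence[int] | None = None,
) -> StrategyRun:
    """Tune → refit → predict for every outer fold of the plan.

    ``outer_folds`` restricts the run to a subset of outer folds (scaled-down
    studies); the default runs them all.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    prior = prior or PriorSpec()
    settings = settings or CVSettings()

    design_all = build_design(pheno)
    pos = match_lines(pheno, markers)
    sub_markers = MarkerMatrix(design_all.line_ids, markers.codes[pos])
    cache = _KernelCache(squared_distance_matrix(sub_markers))
    Y = pheno.values()
    n, nT = Y.shape
    folds = list(outer_folds) if outer_folds is not None else list(range(1, plan.k_outer + 1))

    pred_rows: list[tuple] = []
    rho_rows: list[tuple] = []
    inner_frames: list[pd.DataFrame] = []
    tune_results: dict[int, TuneResult] = {}

    for f in folds:
        test_rows = np.flatnonzero(plan.outer == f)
        train_rows = np.flatnonzero(plan.outer != f)
        if strategy == "NT":
            tr = nt_result()
        else:
            obj = InnerObjective(
                pheno, cache, design_all, train_rows, plan.inner[f], prior, settings, f
            )
            if strategy == "GrS":
                grid = make_grid(settings.grid_start, settings.grid_stop, settings.grid_step)
                tr = tune_grid(obj, grid)
            else:
                tr = tune_bo(
                    obj,
                    bounds=settings.bo_bounds,
                    n_init=settings.bo_n_init,
                    n_iter=settings.bo_n_iter,
                    seed=derive_seed(prior.seed, "bo", f),
                )
            inner_frames.append(obj.log_frame())
        tune_results[f] = tr

        k, keig = cache.get(tr.rho_opt)
        mask = np.zeros((n, nT), dtype=bool)
        mask[test_rows, :] = True
        fit = fit_gibbs(
            pheno,
            k,
            design_all,
            prior=replace(prior, seed=derive_seed(prior.seed, "refit", f)),
            include_ge=settings.include_ge,
            mask=mask,
            k_eig=keig,
        )
        envs = pheno.data["env"].to_numpy()
        for t, trait in enumerate(pheno.trait_names):
            cells = test_rows[~np.isnan(Y[test_rows, t])]
            for r in cells:
                pred_rows.append((f, trait, envs[r], int(r), Y[r, t], fit.y_pred[r, t]))
        rho_rows.append(
            (settings.dataset_name, strategy, "ALL", "Global", f, "rho_opt", tr.rho_opt)
        )

    predictions = pd.DataFrame(
        pred_rows, columns=["fold", "trait", "env", "row", "observed", "predicted"]
    )
    metrics = per_fold_rows(
        predictions, strategy, dataset=settings.dataset_name, global_mode=settings.global_mode
    )
    metrics = pd.concat(
        [metrics, pd.DataFrame(rho_rows, columns=metrics.columns)], ignore_index=True
    )
    inner_log = (
        pd.concat(inner_frames, ignore_index=True)
        if inner_frames
        else pd.DataFrame(
            columns=["fold", "rho", "inner_fold", "row", "trait", "observed", "predicted"]
        )
    )
    return StrategyRun(
        strategy=strategy,
        metrics=metrics,
        predictions=predictions,
        tune_results=tune_results,
        inner_log=inner_log,
    )


def verify_inner_objective(run: StrategyRun, atol: float = 1e-9) -> dict[int, bool]:
    """Leakage audit: recompute each fold's inner objective from the logged
    inner predictions alone and check that the logged evaluations and the
    selected ρ follow from them (argmin with smallest-ρ ties)."""
    out: dict[int, bool] = {}
    if run.inner_log.empty:
        return out
    for f, tr in run.tune_results.items():
        log_f = run.inner_log[run.inner_log["fold"] == f]
        if log_f.empty:
            continue
        ok = True
        recomputed = {}
        for rho, grp in log_f.groupby("rho"):
            fold_vals = []
            for _, sub in grp.groupby("inner_fold"):
                tv = [
                    nrmse(tsub["observed"], tsub["predicted"])
                    for _, tsub in sub.groupby("trait")
                ]
                fold_vals.append(float(np.mean(tv)))
            recomputed[float(rho)] = float(np.mean(fold_vals))
        for rho, val in tr.evaluations:
            rec = recomputed.get(float(rho))
            if rec is None or abs(rec - val) > atol:
                ok = False
        rhos = np.array(sorted(recomputed))
        vals = np.array([recomputed[r] for r in rhos])
        if abs(rhos[int(np.argmin(vals))] - tr.rho_opt) > atol:
            ok = False
        out[f] = ok
    return out
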