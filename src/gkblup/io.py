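"""Tabular input/output and the shared data model.

The pipeline works on three containers:

* :class:`MarkerMatrix` — lines × markers genotype codes (0/1/2, or 0/1 for
  presence/absence panels), the raw material for every kernel.
* :class:`PhenotypeTable` — long-format multi-trait observations, one row per
  (line, environment) cell, canonically ordered first by environment and then
  by line.  Individual trait values may be missing; fully empty rows are not.
* :class:`DesignMatrices` — the incidence matrices of the multi-trait model
  (environment, line, and environment×line interaction), derived from a
  phenotype table.

Phenotype and marker files are plain UTF-8 CSV with a header.  Line ids are
matched between the two files by exact string equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not have the expected columns/layout."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a data-model invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMatrix:
    """Genotype codes for J lines at p markers.

    ``codes[i, j]`` counts copies of the designated allele of marker j carried
    by line i.  Diploid SNP panels use {0, 1, 2}; presence/absence panels use
    {0, 1}.  No missing entries are allowed (inputs are assumed post-QC and
    imputed).
    """

    line_ids: tuple[str, ...]
    codes: np.ndarray  # (J, p) integer array

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValidationError("marker codes must be a 2-D array")
        J, p = codes.shape
        if J < 2:
            raise ValidationError(f"need at least 2 lines, got {J}")
        if p < 1:
            raise ValidationError("need at least one marker")
        if len(self.line_ids) != J:
            raise ValidationError("line_ids length does not match code rows")
        if len(set(self.line_ids)) != J:
            raise ValidationError("duplicated line id in marker matrix")
        if not np.issubdtype(codes.dtype, np.integer):
            if np.isnan(codes.astype(float)).any():
                raise ValidationError("missing marker codes are not allowed")
            rounded = np.rint(codes)
            if not np.allclose(codes, rounded):
                raise ValidationError("marker codes must be integers")
            codes = rounded.astype(np.int64)
        if codes.min() < 0 or codes.max() > 2:
            raise ValidationError("marker codes must lie in {0, 1, 2}")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "line_ids", tuple(str(l) for l in self.line_ids))

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format multi-trait phenotype records.

    ``data`` has columns ``line``, ``env`` and one numeric column per trait,
    sorted by (env, line).  Missing trait values are carried as NaN — they are
    what cross-validation masking and unbalanced designs produce — but a row
    with every trait missing is rejected at construction.
    """

    data: pd.DataFrame
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.data
        traits = tuple(str(t) for t in self.trait_names)
        if len(traits) < 1:
            raise ValidationError("need at least one trait")
        for col in ("line", "env", *traits):
            if col not in df.columns:
                raise FormatError(f"phenotype table lacks column {col!r}")
        df = df.loc[:, ["line", "env", *traits]].copy()
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        for t in traits:
            df[t] = pd.to_numeric(df[t], errors="raise")
        if df.duplicated(subset=["line", "env"]).any():
            dup = df[df.duplicated(subset=["line", "env"], keep=False)]
            pair = (dup.iloc[0]["line"], dup.iloc[0]["env"])
            raise ValidationError(f"duplicated (line, env) pair {pair}")
        if df[list(traits)].isna().all(axis=1).any():
            raise ValidationError("rows with every trait missing are not allowed")
        df = df.sort_values(["env", "line"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "trait_names", traits)

    # -- convenience views ------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def env_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["env"].unique()))

    @property
    def line_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["line"].unique()))

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def values(self) -> np.ndarray:
        """n × nT float array of trait values (NaN = missing)."""
        return self.data[list(self.trait_names)].to_numpy(dtype=float)

    def subset(self, rows: Sequence[int]) -> "PhenotypeTable":
        """Row subset (canonical order is preserved by re-sorting)."""
        sub = self.data.iloc[np.asarray(rows)].reset_index(drop=True)
        return PhenotypeTable(sub, self.trait_names)


@dataclass(frozen=True)
class DesignMatrices:
    """Incidence structure of a phenotype table.

    ``env_idx``/``line_idx`` map each observation row to its environment and
    line position; the dense matrices X_E (n×I), Z_L (n×J) and the
    environment-major interaction incidence Z_EL (n×(J·I)) are materialized on
    demand.  The interaction column for environment e and line l sits at index
    ``e * J + l``.
    """

    env_ids: tuple[str, ...]
    line_ids: tuple[str, ...]
    env_idx: np.ndarray  # (n,) int
    line_idx: np.ndarray  # (n,) int

    @property
    def n_obs(self) -> int:
        return len(self.env_idx)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def X_E(self) -> np.ndarray:
        X = np.zeros((self.n_obs, self.n_envs), dtype=np.int8)
        X[np.arange(self.n_obs), self.env_idx] = 1
        return X

    @property
    def Z_L(self) -> np.ndarray:
        Z = np.zeros((self.n_obs, self.n_lines), dtype=np.int8)
        Z[np.arange(self.n_obs), self.line_idx] = 1
        return Z

    @property
    def Z_EL(self) -> np.ndarray:
        Z = np.zeros((self.n_obs, self.n_envs * self.n_lines), dtype=np.int8)
        cols = self.env_idx * self.n_lines + self.line_idx
        Z[np.arange(self.n_obs), cols] = 1
        return Z

    def line_counts(self) -> np.ndarray:
        """Number of observation rows per line (length J)."""
        return np.bincount(self.line_idx, minlength=self.n_lines)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path, trait_columns: Sequence[str]) -> PhenotypeTable:
    """Read a long-format phenotype CSV.

    The file must have a header with ``line``, ``env`` and the named trait
    columns; additional columns are ignored.  Rows are re-sorted into the
    canonical (env, line) order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"line": str, "env": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty phenotype file") from exc
    missing = [c for c in ("line", "env", *trait_columns) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return PhenotypeTable(df, tuple(trait_columns))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, index=False)


def read_markers(path: str | Path) -> MarkerMatrix:
    """Read a marker CSV: first column line ids, remaining columns codes."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty marker file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a line-id column plus markers")
    ids = df.iloc[:, 0].astype(str).tolist()
    codes = df.iloc[:, 1:]
    try:
        arr = codes.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric marker code") from exc
    if np.isnan(arr).any():
        raise ValidationError(f"{path}: missing marker code")
    if not np.allclose(arr, np.rint(arr)):
        raise ValidationError(f"{path}: non-integer marker code")
    return MarkerMatrix(tuple(ids), arr.astype(np.int64))


def write_markers(markers: MarkerMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        markers.codes,
        columns=[f"m{j}" for j in range(markers.n_markers)],
    )
    df.insert(0, "line", list(markers.line_ids))
    df.to_csv(path, index=False)


def build_design(
    pheno: PhenotypeTable,
    line_ids: Sequence[str] | None = None,
    env_ids: Sequence[str] | None = None,
) -> DesignMatrices:
    """Build the incidence matrices for a phenotype table.

    ``line_ids``/``env_ids`` optionally fix the label universe (needed when a
    row subset must keep the full model dimension, e.g. inside CV folds); they
    must cover every label present in the table.
    """
    lines = tuple(line_ids) if line_ids is not None else pheno.line_ids
    envs = tuple(env_ids) if env_ids is not None else pheno.env_ids
    line_pos = {l: i for i, l in enumerate(lines)}
    env_pos = {e: i for i, e in enumerate(envs)}
    try:
        li = np.array([line_pos[l] for l in pheno.data["line"]], dtype=np.int64)
        ei = np.array([env_pos[e] for e in pheno.data["env"]], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} not in the design universe") from exc
    return DesignMatrices(envs, lines, ei, li)


def match_lines(pheno: PhenotypeTable, markers: MarkerMatrix) -> np.ndarray:
    """Positions of the phenotype table's lines inside the marker matrix.

    Every phenotyped line must be genotyped; marker-only lines are fine (they
    can still be predicted).
    """
    pos = {l: i for i, l in enumerate(markers.line_ids)}
    missing = [l for l in pheno.line_ids if l not in pos]
    if missing:
        raise ValidationError(
            f"{len(missing)} phenotyped line(s) absent from the marker matrix, "
            f"e.g. {missing[:3]}"
        )
    return np.array([pos[l] for l in pheno.line_ids], dtype=np.int64)
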