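"""Expression datasets: container, standardization, delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "standardize", "read_expression", "read_response"]


def standardize(X: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale each column of ``X`` to mean 0, sd 1.

    Parameters
    ----------
    X : (n, p) array
    ddof : int
        Degrees-of-freedom correction for the standard deviation.  The
        default 1 is the sample convention; 0 gives the population one.

    Returns
    -------
    X_std, means, sds
        Standardized matrix and the per-column statistics, so new samples
        can be placed on the training scale (or the transform inverted).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x genes)")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    bad = np.where(sds == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s) at index {bad.tolist()}: zero variance, cannot standardize")
    return (X - means) / sds, means, sds


@dataclass
class ExpressionDataset:
    """Aligned expression matrix and response.

    Attributes
    ----------
    X : (n, p) float array
        Samples by genes.
    y : (n,) float array
        Continuous response, or 0/1 for the binary model.
    gene_ids, sample_ids : lists of str
    standardized : bool
        True once each column of ``X`` has mean 0 and sd 1.
    """

    X: np.ndarray
    y: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 samples and p >= 1 genes, got n={n}, p={p}")
        if self.y.shape[0] != n:
            raise ValueError(f"response length {self.y.shape[0]} != sample count {n}")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("missing or non-finite values are not supported")
        if self.standardized:
            if not (
                np.allclose(self.X.mean(axis=0), 0, atol=1e-8)
                and np.allclose(self.X.std(axis=0, ddof=1), 1, atol=1e-8)
            ):
                raise ValueError("standardized flag set but columns are not mean-0 / sd-1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.y, (0.0, 1.0)).all())

    def standardize(self, ddof: int = 1) -> tuple["ExpressionDataset", np.ndarray, np.ndarray]:
        """Return a standardized copy plus the column means and sds."""
        if self.standardized:
            return self, np.zeros(self.n_genes), np.ones(self.n_genes)
        try:
            Xs, means, sds = standardize(self.X, ddof=ddof)
        except ValueError as exc:
            bad = [self.gene_ids[i] for i in np.where(self.X.std(axis=0) == 0)[0]]
            if bad:
                raise ValueError(f"constant expression for gene(s) {bad}: cannot standardize") from exc
            raise
        return replace(self, X=Xs, standardized=True), means, sds


def read_expression(path: str | Path, sep: str = "\t") -> tuple[pd.DataFrame, list[str], list[str]]:
    """Read an expression matrix: header row of gene ids, first column sample ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no gene columns found")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    return df, [str(g) for g in df.columns], [str(s) for s in df.index]


def read_response(path: str | Path, column: str | None = None, sep: str = "\t") -> pd.Series:
    """Read a response vector.

    Either a headerless one-value-per-line file (``column=None``) or a
    delimited table whose first column holds sample ids and where
    ``column`` names the response.
    """
    if column is None:
        s = pd.read_csv(path, header=None, sep=sep).iloc[:, 0]
        s.index = s.index.astype(str)
        return s.astype(float)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if column not in df.columns:
        raise ValueError(f"{path}: no column named {column!r} (have {list(df.columns)})")
    s = df[column].astype(float)
    s.index = s.index.astype(str)
    return s
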