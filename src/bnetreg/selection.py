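"""Posterior summaries, gene ranking, and evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gibbs import ChainResult

__all__ = ["GeneRanking", "summarize_chain", "select_top_k", "pmse", "acc", "auc"]


@dataclass
class GeneRanking:
    """Per-gene posterior summary ordered by |posterior mean coefficient|.

    ``table`` columns: gene_id, rank, post_mean, post_sd, ci_lower,
    ci_upper.  Ranks are 1..p; ties in |post_mean| are broken by gene
    identifier so output is deterministic across platforms.
    """

    table: pd.DataFrame
    level: float

    def __post_init__(self) -> None:
        t = self.table
        p = len(t)
        if sorted(t["rank"]) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..p")
        absmean = t["post_mean"].abs().to_numpy()
        if not (np.diff(absmean) <= 1e-12).all():
            raise ValueError("|post_mean| must be nonincreasing in rank")
        if not (t["ci_lower"] <= t["ci_upper"]).all():
            raise ValueError("interval lower bounds must not exceed uppers")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, level: float = 0.95) -> "GeneRanking":
        return cls(table=pd.read_csv(path, sep="\t", dtype={"gene_id": str}), level=level)


def summarize_chain(result: ChainResult, level: float = 0.95) -> GeneRanking:
    """Posterior mean, sd and equal-tailed credible interval per gene.

    Intervals are empirical quantiles of the retained draws at
    (1-level)/2 and 1-(1-level)/2 (linear-interpolation quantile rule).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if result.n_draws < 2:
        raise ValueError("need at least 2 retained draws to summarize a chain")
    draws = result.beta
    gene_ids = result.gene_ids or [f"g{j}" for j in range(draws.shape[1])]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    t = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "post_mean": draws.mean(axis=0),
            "post_sd": draws.std(axis=0, ddof=1),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    t["abs_mean"] = t["post_mean"].abs()
    t = t.sort_values(["abs_mean", "gene_id"], ascending=[False, True], kind="mergesort")
    t = t.drop(columns="abs_mean").reset_index(drop=True)
    t.insert(1, "rank", np.arange(1, len(t) + 1))
    return GeneRanking(table=t, level=level)


def select_top_k(ranking: GeneRanking, k: int) -> list[str]:
    """The top-k genes by |posterior mean coefficient|."""
    p = len(ranking.table)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return ranking.table["gene_id"].head(k).tolist()


def pmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Prediction mean square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape[0]} vs {y_pred.shape[0]}")
    if y_true.size == 0:
        raise ValueError("need at least one observation")
    return float(np.mean((y_true - y_pred) ** 2))


def acc(y_true: np.ndarray, p_pred: np.ndarray, threshold: float = 0.5) -> float:
    """Classification accuracy of thresholded probabilities."""
    y_true = np.asarray(y_true).ravel()
    p_pred = np.asarray(p_pred, dtype=float).ravel()
    if y_true.shape != p_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape[0]} vs {p_pred.shape[0]}")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be coded 0/1")
    return float(np.mean((p_pred > threshold).astype(int) == y_true))


def auc(y_true: np.ndarray, p_pred: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The fraction of (positive, negative) pairs whose scores are correctly
    ordered, counting ties as 1/2.
    """
    y_true = np.asarray(y_true).ravel()
    p_pred = np.asarray(p_pred, dtype=float).ravel()
    if y_true.shape != p_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape[0]} vs {p_pred.shape[0]}")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(p_pred)  # midranks handle ties as 1/2
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
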