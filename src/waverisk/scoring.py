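"""Least-squares back-mapping of representative features to per-gene scores.

Given the expression matrix Y (genes x samples) and the representative
feature matrix X (pooled features x samples), the score matrix is the
least-squares solution B of Y ~ B.X, i.e. B = Y.X^T(X.X^T)^-1 — computed
with the Moore-Penrose pseudoinverse because X.X^T is rank-deficient
whenever there are more features than samples. Row means of B are the gene
importance scores; genes are ranked by descending score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def score_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares coefficients B (genes x features) of Y ~ B.X.

    The residual Y - B.X is orthogonal to the rows of X. When X is square
    and invertible this reduces to B = Y.X^-1 exactly.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim != 2 or X.ndim != 2:
        raise ValueError("Y and X must be 2-D")
    if Y.shape[1] != X.shape[1]:
        raise ValueError(
            f"sample-count mismatch: Y has {Y.shape[1]} columns, X has {X.shape[1]}"
        )
    # min-norm solution of min ||Y - B X||_F: B = Y X^+  (X^+ = X^T (X X^T)^+)
    return Y @ np.linalg.pinv(X)


def gene_scores(B: np.ndarray, gene_ids) -> pd.DataFrame:
    """Row-mean scores and descending 1-based ranks; ties broken by gene id.

    Returns a DataFrame indexed by rank order with columns gene_id, score,
    rank.
    """
    B = np.asarray(B, dtype=float)
    if B.size == 0:
        raise ValueError("empty score matrix")
    gene_ids = np.asarray(gene_ids, dtype=object)
    if len(gene_ids) != B.shape[0]:
        raise ValueError("gene_ids length does not match score-matrix rows")
    scores = B.mean(axis=1)
    tbl = pd.DataFrame({"gene_id": gene_ids, "score": scores})
    tbl = tbl.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return tbl.reset_index(drop=True)


def top_n_genes(score_table: pd.DataFrame, n: int) -> list:
    """The first n gene ids by rank."""
    p = len(score_table)
    if not 1 <= n <= p:
        raise ValueError(f"n must be in [1, {p}], got {n}")
    return score_table.sort_values("rank")["gene_id"].head(n).tolist()


def kendall_tau_stability(ranked_lists, k: int = 100) -> pd.DataFrame:
    """Pairwise Kendall tau-b between the top-k portions of full rankings.

    Each input is a full gene ranking (best first) over a shared universe.
    For every pair, the union of the two top-k sets is formed and the two
    full-list rank vectors over that union are compared with Kendall's
    tau-b (two-sided p-value). Returns a DataFrame with columns
    list_i, list_j, tau, p_value.
    """
    lists = [list(l) for l in ranked_lists]
    if len(lists) < 2:
        raise ValueError("need at least two rankings")
    rank_maps = [{g: r for r, g in enumerate(l)} for l in lists]
    universe = set(lists[0])
    for l in lists[1:]:
        if not set(l) & universe:
            raise ValueError("rankings share no genes; check the inputs")
    rows = []
    for i in range(len(lists)):
        for j in range(i + 1, len(lists)):
            union = sorted(set(lists[i][:k]) | set(lists[j][:k]))
            missing = [g for g in union if g not in rank_maps[i] or g not in rank_maps[j]]
            if missing:
                raise ValueError(f"genes absent from one ranking: {missing[:5]}")
            ri = [rank_maps[i][g] for g in union]
            rj = [rank_maps[j][g] for g in union]
            tau, p = stats.kendalltau(ri, rj)
            rows.append({"list_i": i, "list_j": j, "tau": float(tau), "p_value": float(p)})
    return pd.DataFrame(rows)
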