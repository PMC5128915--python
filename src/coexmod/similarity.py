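"""Affine-invariant expression similarity and co-expression networks.

Two genes are considered co-expressed when one profile is (close to) an
affine transform of the other — a shift (``y = x + b``), a scaling
(``y = a*x``), or both (``y = a*x + b``).  The default measure is the
absolute Pearson correlation over pairwise-complete positions, which is
exactly 1 for any noise-free affine relation with ``a != 0`` and decays
with noise; absolute Spearman is available as a rank-based robust
alternative.  The measure is a pluggable strategy so other
pattern-similarity scores can be dropped in.

The co-expression network (CEN) is the undirected graph whose edges
connect gene pairs with similarity >= delta (inclusive threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def abs_pearson(x, y) -> float:
    """|Pearson r| over pairwise-complete positions, clamped to [0, 1].

    Returns NaN (undefined) when fewer than 2 complete positions remain
    or either profile is constant over them — a constant gene carries no
    pattern and must not become a spurious hub.
    """
    xc, yc = _pairwise_complete(x, y)
    if xc.size < 2:
        return float("nan")
    sx = xc - xc.mean()
    sy = yc - yc.mean()
    nx = np.sqrt(sx @ sx)
    ny = np.sqrt(sy @ sy)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    r = (sx @ sy) / (nx * ny)
    return float(min(abs(r), 1.0))


def abs_spearman(x, y) -> float:
    """|Spearman rho| over pairwise-complete positions, clamped to [0, 1]."""
    xc, yc = _pairwise_complete(x, y)
    if xc.size < 2:
        return float("nan")
    if np.all(xc == xc[0]) or np.all(yc == yc[0]):
        return float("nan")
    rho = stats.spearmanr(xc, yc).statistic
    if not np.isfinite(rho):
        return float("nan")
    return float(min(abs(rho), 1.0))


MEASURES = {"abspearson": abs_pearson, "absspearman": abs_spearman}


def expression_similarity(x, y, measure: str = "abspearson") -> float:
    """Similarity in [0, 1] between two expression profiles.

    Equals 1 (to 1e-12) whenever ``y = a*x + b`` elementwise with
    ``a != 0``; symmetric; invariant to a common permutation of both
    profiles.  NaN marks an undefined score (treated as below any
    threshold downstream).
    """
    try:
        fn = MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    return fn(x, y)


def n_pair_evaluations(n_genes: int) -> int:
    """Ordered all-vs-all evaluation count for an n-gene matrix (n^2).

    Reported so users can gauge the cost of the similarity stage before
    running it; the stage itself computes each unordered pair once.
    """
    return int(n_genes) * int(n_genes)


def similarity_matrix(values, gene_ids=None, measure: str = "abspearson") -> pd.DataFrame:
    """Symmetric gene x gene similarity matrix in [0, 1].

    Parameters
    ----------
    values : array-like (n_genes, n_samples) or ExpressionMatrix or DataFrame
        Expression profiles in rows; NaN marks missing measurements.
    gene_ids : sequence of str, optional
        Row labels; inferred from the input when it carries an index.
    measure : {"abspearson", "absspearman"}

    Equal to the elementwise application of
    :func:`expression_similarity` to every unordered pair; deterministic.
    Undefined pair scores are NaN.  The diagonal is 1 for genes with a
    defined self-similarity (>= 2 finite values, non-constant), NaN
    otherwise.
    """
    if hasattr(values, "data") and isinstance(getattr(values, "data"), pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(values.data.index)
        values = values.data.to_numpy(dtype=float)
    elif isinstance(values, pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(values.index)
        values = values.to_numpy(dtype=float)
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D genes x samples array")
    n = X.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]

    if measure == "abspearson" and np.isfinite(X).all():
        S = _abs_pearson_matrix(X)
    else:
        fn = MEASURES.get(measure)
        if fn is None:
            raise ValueError(f"unknown measure {measure!r}")
        S = np.full((n, n), np.nan)
        for i in range(n):
            S[i, i] = 1.0 if _self_defined(X[i]) else np.nan
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = fn(X[i], X[j])
    return pd.DataFrame(S, index=gene_ids, columns=gene_ids)


def _self_defined(x) -> bool:
    x = x[np.isfinite(x)]
    return x.size >= 2 and not np.all(x == x[0])


def _abs_pearson_matrix(X: np.ndarray) -> np.ndarray:
    # vectorized complete-data fast path
    n = X.shape[0]
    C = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((C * C).sum(axis=1))
    ok = norms > 0
    denom = np.where(ok, norms, 1.0)
    U = C / denom[:, None]
    S = np.abs(U @ U.T)
    np.clip(S, 0.0, 1.0, out=S)
    S[~ok, :] = np.nan
    S[:, ~ok] = np.nan
    idx = np.arange(n)
    S[idx[ok], idx[ok]] = 1.0
    return S


@dataclass
class CoexpressionNetwork:
    """delta-thresholded adjacency over a similarity matrix."""

    gene_ids: list[str]
    adjacency: np.ndarray  # symmetric bool, zero diagonal
    delta: float

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def build_network(scores, delta: float) -> CoexpressionNetwork:
    """Threshold a similarity matrix into a co-expression network.

    An edge connects genes i != j iff ``scores[i, j] >= delta``
    (inclusive).  NaN scores never produce an edge.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    if isinstance(scores, pd.DataFrame):
        gene_ids = list(scores.index)
        S = scores.to_numpy(dtype=float)
    else:
        S = np.asarray(scores, dtype=float)
        gene_ids = [f"g{i}" for i in range(S.shape[0])]
    with np.errstate(invalid="ignore"):
        A = S >= delta
    np.fill_diagonal(A, False)
    A = A & A.T  # guard against asymmetric input
    return CoexpressionNetwork(gene_ids=gene_ids, adjacency=A, delta=delta)


def write_similarity(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="GENE", na_rep="NA")


def read_similarity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
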