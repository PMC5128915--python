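"""Prioritization of border genes by differential expression and
semantic coherence.

Border genes — module members with low co-expression connectivity — are
pooled across modules, ranked by expression variance between normal and
disease samples, and the top k are carried into a GO (Biological
Process) Lin semantic-similarity matrix.  Genes participating in at
least one pair whose semantic score reaches beta, the mean of all
computed pairwise scores, are reported as *interesting*: weak
co-expression partners that nonetheless share function with the pool,
the profile expected of disease-relevant genes missed by pure
co-expression analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix
from .ontology import AnnotationIndex, gene_semantic_matrix


@dataclass
class InterestingGeneReport:
    border_pool: set[str]
    ranked: list[tuple[str, float]]
    k_selected: list[str]
    mapped: list[str]
    unmapped: list[str]
    beta: float
    interesting: set[str]
    provenance: dict[str, int] = field(default_factory=dict)
    semantic: pd.DataFrame | None = None


def rank_by_variance(border, m: ExpressionMatrix, k: int = 2000,
                     stat: str = "variance"):
    """Rank border genes by a differential-expression statistic.

    ``stat="variance"`` (default) scores each gene by its sample
    variance pooled over normal and disease samples; ``stat="meandiff"``
    by the absolute difference of class means.  Ties break
    lexicographically on gene ID.  Returns the full descending ranking
    and the top-k gene list; if the pool holds <= k genes, all pass
    (with a warning rather than an error).
    """
    if m.sample_class is None:
        raise ValueError(
            "sample class labels are required; supply them with --classes "
            "(a two-column sample_id<TAB>class TSV)")
    border = [g for g in border if g in m.data.index]
    if stat == "variance":
        scores = m.data.loc[border].var(axis=1, ddof=1, skipna=True)
    elif stat == "meandiff":
        classes = m.sample_class
        levels = list(dict.fromkeys(classes))
        if len(levels) != 2:
            raise ValueError(f"meandiff needs exactly 2 classes, got {levels}")
        a = m.data.loc[border, classes == levels[0]].mean(axis=1, skipna=True)
        b = m.data.loc[border, classes == levels[1]].mean(axis=1, skipna=True)
        scores = (a - b).abs()
    else:
        raise ValueError("stat must be 'variance' or 'meandiff'")
    scores = scores.fillna(0.0)
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(order) < k:
        warnings.warn(f"border pool ({len(order)}) smaller than k={k}; "
                      "keeping all", stacklevel=2)
    top = [g for g, _ in order[:k]]
    return order, top


def map_ids(genes, mapping: pd.DataFrame | dict | None):
    """Translate gene IDs through a two-column mapping table.

    ``mapping`` is a DataFrame whose first two columns are (source,
    target), a dict, or None for the identity.  A source mapping to
    several targets keeps the first by file order (with a warning);
    unmapped genes are reported and dropped from the semantic step.
    Returns (mapped, unmapped, gene->target dict).
    """
    if mapping is None:
        return list(genes), [], {g: g for g in genes}
    if isinstance(mapping, pd.DataFrame):
        src = mapping.iloc[:, 0].astype(str)
        dst = mapping.iloc[:, 1].astype(str)
        table: dict[str, str] = {}
        dup = 0
        for s, d in zip(src, dst):
            if s in table:
                dup += 1
                continue
            table[s] = d
        if dup:
            warnings.warn(f"{dup} source IDs mapped to multiple targets; "
                          "kept first by file order", stacklevel=2)
    else:
        table = dict(mapping)
    mapped, unmapped, out = [], [], {}
    for g in genes:
        if g in table:
            mapped.append(table[g])
            out[g] = table[g]
        else:
            unmapped.append(g)
    return mapped, unmapped, out


def select_interesting(sem: pd.DataFrame, rule: str = "any"):
    """Apply the beta mean-threshold rule to a semantic matrix.

    beta is the mean of the defined (non-NaN) upper-triangle
    off-diagonal scores.  With ``rule="any"`` (default) a gene is
    interesting iff it participates in >= 1 pair scoring >= beta
    (inclusive); ``rule="rowmean"`` requires the gene's mean pairwise
    score to reach beta.  Returns (beta, interesting gene set).
    """
    S = sem.to_numpy(dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need >= 2 genes to compute beta")
    iu = np.triu_indices(n, k=1)
    vals = S[iu]
    defined = np.isfinite(vals)
    if not defined.any():
        raise ValueError("all pairwise semantic scores are undefined")
    beta = float(vals[defined].mean())
    off = S.copy()
    np.fill_diagonal(off, np.nan)
    # tolerance keeps ">= beta" inclusive when beta ties a score exactly
    cut = beta - 1e-12
    with np.errstate(invalid="ignore"):
        if rule == "any":
            hit = np.nansum(off >= cut, axis=1) > 0
        elif rule == "rowmean":
            row_mean = np.array([np.nan if not np.isfinite(r).any()
                                 else np.nanmean(r) for r in off])
            hit = row_mean >= cut
        else:
            raise ValueError("rule must be 'any' or 'rowmean'")
    return beta, {sem.index[i] for i in np.flatnonzero(hit)}


class BorderGenePrioritizer(BaseEstimator):
    """End-of-pipeline selector: border pool -> interesting genes.

    Parameters
    ----------
    k : int
        Number of top-variance differentially expressed genes retained
        (default 2000).
    de_stat : {"variance", "meandiff"}
    combine : {"bma", "max"}
        Gene-level semantic combination rule.
    rule : {"any", "rowmean"}
        Interesting-gene membership rule against beta.

    ``fit`` consumes the border pool, the (preprocessed) expression
    matrix with sample classes, the annotation index and an optional ID
    mapping; fitted attributes expose beta_, interesting_ and report_.
    """

    def __init__(self, k: int = 2000, de_stat: str = "variance",
                 combine: str = "bma", rule: str = "any"):
        self.k = k
        self.de_stat = de_stat
        self.combine = combine
        self.rule = rule

    def fit(self, border_pool, expression: ExpressionMatrix,
            annotations: AnnotationIndex, mapping=None, provenance=None):
        ranked, top = rank_by_variance(border_pool, expression, k=self.k,
                                       stat=self.de_stat)
        mapped, unmapped, table = map_ids(top, mapping)
        var_of = dict(ranked)
        self._var_by_target = {t: var_of[s] for s, t in table.items()
                               if s in var_of}
        sem, dropped = gene_semantic_matrix(mapped, annotations,
                                            combine=self.combine)
        beta, interesting = select_interesting(sem, rule=self.rule)
        self.beta_ = beta
        self.interesting_ = interesting
        self.semantic_ = sem
        self.report_ = InterestingGeneReport(
            border_pool=set(border_pool), ranked=ranked, k_selected=top,
            mapped=mapped, unmapped=unmapped + dropped, beta=beta,
            interesting=interesting, provenance=dict(provenance or {}),
            semantic=sem)
        return self

    def report_frame(self) -> pd.DataFrame:
        """Per-gene table: variance score, semantic summaries, flag."""
        rep = self.report_
        S = rep.semantic
        rows = []
        var_of = getattr(self, "_var_by_target", dict(rep.ranked))
        for g in S.index:
            row = S.loc[g].drop(labels=[g], errors="ignore")
            rows.append({
                "gene": g,
                "variance_score": var_of.get(g, np.nan),
                "mean_semantic": row.mean(skipna=True),
                "max_semantic": row.max(skipna=True),
                "interesting": int(g in rep.interesting),
            })
        return pd.DataFrame(rows)
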