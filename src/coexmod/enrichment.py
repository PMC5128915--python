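"""Hypergeometric GO-term enrichment with Benjamini-Hochberg FDR.

For a module of size n drawn from a population of N annotated genes, of
which K carry a term, the enrichment p-value is the exact upper tail
P[X >= hits] of Hypergeometric(N, K, n).  q-values are BH-adjusted
within one module's family of tested terms, matching how per-module
false-discovery rates are usually tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationIndex


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    module_hits: int
    module_size: int
    term_size: int
    population: int
    p: float
    q: float


def hypergeom_p(hits: int, module_size: int, term_size: int,
                population: int) -> float:
    """Exact upper-tail P[X >= hits] for Hypergeometric(population,
    term_size, module_size); no normal approximation."""
    if not (0 <= hits <= min(module_size, term_size)
            and max(module_size, term_size) <= population):
        raise ValueError(
            f"inconsistent counts: hits={hits}, module={module_size}, "
            f"term={term_size}, population={population}")
    if hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(hits - 1, population, term_size,
                                    module_size))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_i = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_module(module_genes, ann: AnnotationIndex,
                  min_hits: int = 1) -> pd.DataFrame:
    """Per-term enrichment of one module against the annotation corpus.

    The population is every gene with >= 1 annotation in the namespace
    (not every gene on the array); term membership uses propagated
    (true-path) annotations.  Returns one row per term with >= min_hits
    module hits, sorted by p ascending with term-ID tie-break; q over
    this module's term family.
    """
    in_corpus = [g for g in module_genes if g in ann.propagated]
    if not in_corpus:
        import warnings
        warnings.warn("no module gene found in the annotation corpus",
                      stacklevel=2)
        return _empty_frame()
    module_size = len(in_corpus)
    population = ann.corpus_size
    hits_per_term: dict[str, int] = {}
    for g in in_corpus:
        for t in ann.propagated[g]:
            hits_per_term[t] = hits_per_term.get(t, 0) + 1
    rows = []
    for term, hits in hits_per_term.items():
        if hits < min_hits:
            continue
        term_size = ann.term_count[term]
        p = hypergeom_p(hits, module_size, term_size, population)
        rows.append((term, ann.ontology.names.get(term, term), hits,
                     module_size, term_size, population, p))
    if not rows:
        return _empty_frame()
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "module_hits",
                                     "module_size", "term_size",
                                     "population", "p"])
    df["q"] = bh_qvalues(df["p"].to_numpy())
    df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["term_id", "term_name", "module_hits",
                                 "module_size", "term_size", "population",
                                 "p", "q"])


def enrich_all_modules(modules, ann: AnnotationIndex) -> pd.DataFrame:
    """Concatenate per-module enrichment tables with a module_no column."""
    frames = []
    for m in modules:
        df = enrich_module(sorted(m.members), ann)
        df.insert(0, "module_no", m.module_id)
        frames.append(df)
    if not frames:
        return _empty_frame()
    return pd.concat(frames, ignore_index=True)
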