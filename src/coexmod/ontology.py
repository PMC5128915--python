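"""Gene Ontology parsing, information content and Lin semantic similarity.

A term's information content is the negative log (base 2) of its
annotation frequency in the corpus under the true-path rule: a gene
annotated to a term counts for every ancestor of that term, so the
namespace root has frequency 1 and Ic 0.  The Lin similarity of two
terms is

    sim(t1, t2) = 2 * Ic(MICA) / (Ic(t1) + Ic(t2))

where MICA is their common ancestor of maximal Ic.  Gene-level
similarity combines the term-pair scores of the two genes' annotation
sets, by default with the best-match average (BMA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import obonet
import pandas as pd

NAMESPACES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}
_ASPECT_TO_NS = {"P": "biological_process", "F": "molecular_function",
                 "C": "cellular_component"}


@dataclass
class OntologyIndex:
    """is_a hierarchy of GO terms, partitioned by namespace."""

    is_a_parents: dict[str, set[str]]
    namespace: dict[str, str]
    roots: dict[str, str]  # namespace -> root term
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term``, including the term itself."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = list(self.is_a_parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.is_a_parents.get(t, ()))
        res = frozenset(out)
        self._anc_cache[term] = res
        return res


def load_obo(path, include_part_of: bool = False) -> OntologyIndex:
    """Parse an OBO 1.2/1.4 ontology into an is_a hierarchy.

    Obsolete terms are dropped (obonet's default).  Only ``is_a`` edges
    are used unless ``include_part_of`` is set.  Raises ValueError,
    listing the offending terms, if the hierarchy contains a cycle.
    """
    graph = obonet.read_obo(path)
    keep_rels = {"part_of"} if include_part_of else set()
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    for term, attrs in graph.nodes(data=True):
        namespace[term] = attrs.get("namespace", "biological_process")
        names[term] = attrs.get("name", term)
        parents.setdefault(term, set())
    # obonet edge direction: child -> parent, keyed by relation
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a" or rel in keep_rels:
            if parent in namespace:
                parents.setdefault(child, set()).add(parent)

    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    dag.add_nodes_from(parents)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"is_a cycle detected: {cycle}")

    roots: dict[str, str] = {}
    for term, ps in parents.items():
        same_ns_parents = {p for p in ps if namespace[p] == namespace[term]}
        if not same_ns_parents:
            ns = namespace[term]
            if ns in roots and roots[ns] != term:
                # multiple apex terms: keep the lexicographically smallest
                roots[ns] = min(roots[ns], term)
            else:
                roots[ns] = term
    return OntologyIndex(is_a_parents=parents, namespace=namespace,
                         roots=roots, names=names)


@dataclass
class AnnotationIndex:
    """Gene -> GO-term annotations with true-path propagation.

    ``term_count[t]`` is the number of distinct genes annotated at or
    below ``t``; ``corpus_size`` is the number of genes annotated
    anywhere in the namespace (equivalently ``term_count[root]``).
    """

    ontology: OntologyIndex
    namespace: str
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    term_count: dict[str, int]
    corpus_size: int
    n_skipped_unknown: int = 0

    @property
    def genes(self) -> set[str]:
        return set(self.direct)


def load_annotations(path, ontology: OntologyIndex, namespace: str = "BP",
                     exclude_iea: bool = False) -> AnnotationIndex:
    """Read gene->term annotations from GAF 2.x or a two-column TSV.

    Annotations to terms absent from the ontology raise a warning and
    are skipped (counted in ``n_skipped_unknown``).  Genes with no
    annotation in the requested namespace are excluded from the corpus.
    """
    ns_long = NAMESPACES.get(namespace, namespace)
    pairs, n_unknown = _read_annotation_pairs(path, ontology, ns_long,
                                              exclude_iea)
    return build_annotation_index(pairs, ontology, namespace,
                                  n_skipped_unknown=n_unknown)


def _read_annotation_pairs(path, ontology, ns_long, exclude_iea):
    pairs: list[tuple[str, str]] = []
    n_unknown = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) >= 15:  # GAF: col 2 = gene, 5 = term, 7 = evidence, 9 = aspect
                gene, term, evidence, aspect = cols[1], cols[4], cols[6], cols[8]
                if exclude_iea and evidence == "IEA":
                    continue
                if aspect and _ASPECT_TO_NS.get(aspect) != ns_long:
                    continue
            elif len(cols) >= 2:
                gene, term = cols[0], cols[1]
            else:
                continue
            if term not in ontology.namespace:
                n_unknown += 1
                continue
            if ontology.namespace[term] != ns_long:
                continue
            pairs.append((gene, term))
    if n_unknown:
        warnings.warn(f"skipped {n_unknown} annotations to unknown terms",
                      stacklevel=2)
    return pairs, n_unknown


def build_annotation_index(pairs, ontology: OntologyIndex, namespace: str = "BP",
                           n_skipped_unknown: int = 0) -> AnnotationIndex:
    """Index (gene, term) pairs: propagate to ancestors and count."""
    direct: dict[str, set[str]] = {}
    for gene, term in pairs:
        direct.setdefault(gene, set()).add(term)
    propagated = {g: set().union(*(ontology.ancestors(t) for t in ts))
                  for g, ts in direct.items()}
    term_count: dict[str, int] = {}
    for ts in propagated.values():
        for t in ts:
            term_count[t] = term_count.get(t, 0) + 1
    return AnnotationIndex(ontology=ontology, namespace=namespace,
                           direct=direct, propagated=propagated,
                           term_count=term_count, corpus_size=len(direct),
                           n_skipped_unknown=n_skipped_unknown)


def information_content(term: str, ann: AnnotationIndex) -> float:
    """Ic(t) = -log2(term_count(t) / corpus_size); NaN when the term
    annotates no gene in the corpus (pairs touching it are skipped)."""
    if ann.corpus_size == 0:
        raise ValueError("empty annotation corpus")
    count = ann.term_count.get(term, 0)
    if count == 0:
        return float("nan")
    return float(-np.log2(count / ann.corpus_size)) + 0.0


def lin_similarity(t1: str, t2: str, ann: AnnotationIndex) -> float:
    """Lin term similarity: 2*Ic(MICA) / (Ic(t1) + Ic(t2)) in [0, 1].

    Two root terms (both Ic 0) score 0 by convention.  Cross-namespace
    pairs are an error: they share no ancestor and the comparison is
    meaningless.
    """
    ont = ann.ontology
    if ont.namespace.get(t1) != ont.namespace.get(t2):
        raise ValueError(f"cross-namespace pair: {t1} ({ont.namespace.get(t1)}) "
                         f"vs {t2} ({ont.namespace.get(t2)})")
    ic1 = information_content(t1, ann)
    ic2 = information_content(t2, ann)
    if not (np.isfinite(ic1) and np.isfinite(ic2)):
        return float("nan")
    if ic1 + ic2 == 0.0:
        return 0.0
    common = ont.ancestors(t1) & ont.ancestors(t2)
    ics = [information_content(t, ann) for t in common]
    ics = [v for v in ics if np.isfinite(v)]
    mica_ic = max(ics, default=0.0)
    return float(min(2.0 * mica_ic / (ic1 + ic2), 1.0))


def gene_semantic_matrix(genes, ann: AnnotationIndex, combine: str = "bma"):
    """Gene x gene semantic similarity over direct annotation sets.

    Parameters
    ----------
    genes : sequence of str
    ann : AnnotationIndex
    combine : {"bma", "max"}
        BMA (best-match average): for each term of one gene take its
        best Lin match in the other gene's set, then average the two
        directions.  "max" takes the single best term pair.

    Returns
    -------
    (scores, dropped) : (DataFrame, list of str)
        Symmetric matrix in [0, 1] over the genes that have at least
        one annotation in the corpus; the rest are listed in ``dropped``.
        Invariant to within-gene term-set ordering.  The diagonal is 1
        for genes with >= 1 informative (Ic > 0) term.
    """
    if combine not in ("bma", "max"):
        raise ValueError("combine must be 'bma' or 'max'")
    kept, dropped = [], []
    for g in genes:
        (kept if ann.direct.get(g) else dropped).append(g)
    term_sets = {g: sorted(ann.direct[g]) for g in kept}

    @lru_cache(maxsize=None)
    def term_sim(a: str, b: str) -> float:
        if a > b:
            a, b = b, a
        return lin_similarity(a, b, ann)

    n = len(kept)
    S = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            M = np.array([[term_sim(ta, tb) for tb in term_sets[kept[j]]]
                          for ta in term_sets[kept[i]]])
            fin = np.isfinite(M)
            if not fin.any():
                continue
            if combine == "max":
                S[i, j] = S[j, i] = M[fin].max()
            else:
                # best match per term, skipping terms with no defined pair
                row_best = [M[r][fin[r]].max() for r in range(M.shape[0])
                            if fin[r].any()]
                col_best = [M[:, c][fin[:, c]].max() for c in range(M.shape[1])
                            if fin[:, c].any()]
                S[i, j] = S[j, i] = 0.5 * (float(np.mean(row_best))
                                           + float(np.mean(col_best)))
    return pd.DataFrame(S, index=kept, columns=kept), dropped
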