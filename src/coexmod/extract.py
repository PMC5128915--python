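"""Module extraction by iterative threshold decrement.

The extractor sweeps the edge threshold delta downwards (by default
0.9, 0.8, ..., 0.5 in steps of alpha = 0.1).  At each delta it rebuilds
the co-expression network over the genes not yet assigned to a module
and repeatedly (i) picks a *core* gene — the unassigned gene of maximum
degree, provided that degree reaches the minimum neighborhood threshold
rho — and (ii) grows a module as the connected component containing the
core.  Members whose degree falls below rho are flagged as *border*
genes: weakly co-expressed module members that are the candidates for
downstream semantic prioritization.  Modules are pairwise disjoint and
genes assigned at a higher delta are never reassigned at a lower one.

:class:`ThresholdDecrementExtractor` packages the procedure as a
scikit-learn style clusterer; :func:`extract_modules` is the underlying
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .similarity import CoexpressionNetwork, build_network, similarity_matrix


@dataclass
class THDConfig:
    """Threshold-decrement schedule and neighborhood threshold.

    delta runs from ``delta_start`` down to ``delta_end`` in steps of
    ``alpha``; ``rho`` is the minimum degree a gene needs to qualify as
    a module core, and the degree below which a member is a border gene.
    """

    delta_start: float = 0.9
    delta_end: float = 0.5
    alpha: float = 0.1
    rho: int = 3
    degree_scope: str = "unassigned"  # or "full"

    def __post_init__(self):
        if not (0.0 < self.delta_end <= self.delta_start <= 1.0):
            raise ValueError(
                f"need 0 < delta_end <= delta_start <= 1, got "
                f"({self.delta_start}, {self.delta_end})"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.degree_scope not in ("unassigned", "full"):
            raise ValueError("degree_scope must be 'unassigned' or 'full'")

    def delta_schedule(self) -> list[float]:
        deltas = []
        d = self.delta_start
        while d >= self.delta_end - 1e-9:
            deltas.append(round(d, 12))
            d -= self.alpha
        return deltas


@dataclass
class GeneModule:
    """One extracted module: core gene, member set, border subset."""

    module_id: int
    core_gene: str
    members: set[str]
    border_genes: set[str]
    delta: float
    core_degree: int
    degrees: dict[str, int] = field(default_factory=dict)


def select_core(net: CoexpressionNetwork, unassigned: set[str], rho: int):
    """Pick the unassigned gene of maximum degree, if it reaches rho.

    Degrees are counted on the subgraph induced by ``unassigned`` (a
    module cannot recruit already-assigned genes, so edges to them do
    not count).  Ties break to the lexicographically smallest gene ID;
    returns None when no unassigned gene has degree >= rho.
    """
    if not unassigned:
        return None
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    sel = np.array(sorted(idx[g] for g in unassigned))
    sub = net.adjacency[np.ix_(sel, sel)]
    degs = sub.sum(axis=1)
    best = degs.max() if degs.size else 0
    if best < rho:
        return None
    cands = [net.gene_ids[sel[i]] for i in np.flatnonzero(degs == best)]
    return min(cands)


def grow_module(net: CoexpressionNetwork, core: str, unassigned: set[str]) -> set[str]:
    """Members of the module seeded at ``core``: the connected component
    of the unassigned-restricted graph containing the core (multi-hop
    inclusion; the border-gene notion refers to neighbors of non-core
    members, so membership is not limited to the core's direct
    neighborhood)."""
    if core not in unassigned:
        raise ValueError(f"core gene {core!r} is not unassigned")
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    sel = np.array(sorted(idx[g] for g in unassigned))
    sub = net.adjacency[np.ix_(sel, sel)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    pos = {int(s): k for k, s in enumerate(sel)}
    core_label = labels[pos[idx[core]]]
    return {net.gene_ids[sel[k]] for k in np.flatnonzero(labels == core_label)}


def mark_border(net: CoexpressionNetwork, members: set[str], rho: int,
                scope: str = "unassigned", unassigned: set[str] | None = None) -> set[str]:
    """Border genes of a module: members with degree < rho.

    With ``scope="unassigned"`` (default) degrees are counted on the
    same unassigned-restricted graph the module was grown from; with
    ``scope="full"`` they are counted on the whole network at delta.
    Every member has >= 1 edge by construction, so rho = 1 always yields
    an empty border set.
    """
    degs = _member_degrees(net, members, scope, unassigned)
    return {g for g, d in degs.items() if d < rho}


def _member_degrees(net, members, scope="unassigned", unassigned=None):
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    if scope == "full" or unassigned is None:
        context = set(net.gene_ids)
    else:
        context = set(unassigned)
    sel = np.array(sorted(idx[g] for g in context))
    sub = net.adjacency[np.ix_(sel, sel)]
    degs = sub.sum(axis=1)
    pos = {net.gene_ids[s]: k for k, s in enumerate(sel)}
    return {g: int(degs[pos[g]]) for g in members}


def extract_modules(scores, config: THDConfig | None = None):
    """Run the full threshold-decrement extraction.

    Parameters
    ----------
    scores : DataFrame or array
        Symmetric similarity matrix in [0, 1] (NaN = undefined pair).
    config : THDConfig

    Returns
    -------
    modules : list of GeneModule
    unassigned : set of str
        Genes never assigned by the time delta reaches ``delta_end``;
        they are reported, not forced into a leftover module.
    """
    if config is None:
        config = THDConfig()
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(np.asarray(scores, dtype=float))
        scores.index = scores.columns = [f"g{i}" for i in range(len(scores))]
    gene_ids = list(scores.index)
    unassigned = set(gene_ids)
    modules: list[GeneModule] = []
    for delta in config.delta_schedule():
        # adjacency is rebuilt from the same similarity matrix; only the
        # threshold changes between outer iterations
        net = build_network(scores, delta)
        while True:
            core = select_core(net, unassigned, config.rho)
            if core is None:
                break
            members = grow_module(net, core, unassigned)
            degs = _member_degrees(net, members, config.degree_scope, unassigned)
            border = {g for g, d in degs.items() if d < config.rho}
            modules.append(GeneModule(
                module_id=len(modules) + 1,
                core_gene=core,
                members=members,
                border_genes=border,
                delta=delta,
                core_degree=degs[core],
                degrees=degs,
            ))
            unassigned -= members
    return modules, unassigned


def modules_to_frame(modules, unassigned=()) -> pd.DataFrame:
    """Flat table: module_id, gene_id, role in {core, member, border}, delta."""
    rows = []
    for m in modules:
        for g in sorted(m.members):
            role = "core" if g == m.core_gene else (
                "border" if g in m.border_genes else "member")
            rows.append((m.module_id, g, role, m.delta, m.degrees.get(g)))
    for g in sorted(unassigned):
        rows.append((0, g, "unassigned", np.nan, None))
    return pd.DataFrame(rows, columns=["module_id", "gene_id", "role",
                                       "delta", "degree"])


class ThresholdDecrementExtractor(BaseEstimator, ClusterMixin):
    """Co-expression module extraction as a scikit-learn clusterer.

    ``fit(X)`` takes a genes x conditions expression matrix (rows are
    the objects being clustered) — or, with ``measure="precomputed"``,
    a symmetric similarity matrix — and populates ``labels_`` with a
    module index per gene (-1 for genes left unassigned).

    Parameters
    ----------
    delta_start, delta_end, alpha : float
        Similarity-threshold schedule (defaults 0.9 down to 0.5 by 0.1).
    rho : int
        Minimum neighborhood threshold (default 3).
    measure : {"abspearson", "absspearman", "precomputed"}
    degree_scope : {"unassigned", "full"}
        Graph on which core/border degrees are counted.

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,)
        Module index per gene, -1 for unassigned.
    modules_ : list of GeneModule
    unassigned_ : set of str
    similarity_ : DataFrame
        The gene x gene similarity matrix used.
    gene_ids_ : list of str
    """

    def __init__(self, delta_start=0.9, delta_end=0.5, alpha=0.1, rho=3,
                 measure="abspearson", degree_scope="unassigned"):
        self.delta_start = delta_start
        self.delta_end = delta_end
        self.alpha = alpha
        self.rho = rho
        self.measure = measure
        self.degree_scope = degree_scope

    def _config(self) -> THDConfig:
        return THDConfig(delta_start=self.delta_start, delta_end=self.delta_end,
                         alpha=self.alpha, rho=self.rho,
                         degree_scope=self.degree_scope)

    def fit(self, X, y=None):
        config = self._config()  # validates parameters
        if self.measure == "precomputed":
            if isinstance(X, pd.DataFrame):
                S = X.astype(float)
            else:
                S = pd.DataFrame(np.asarray(X, dtype=float))
                S.index = S.columns = [f"g{i}" for i in range(len(S))]
            arr = S.to_numpy()
            off = arr[~np.eye(len(S), dtype=bool)]
            off = off[np.isfinite(off)]
            if off.size and (off.min() < 0 or off.max() > 1 + 1e-9):
                raise ValueError("precomputed similarities must lie in [0, 1]")
        else:
            S = similarity_matrix(X, measure=self.measure)
        self.similarity_ = S
        self.gene_ids_ = list(S.index)
        self.modules_, self.unassigned_ = extract_modules(S, config)
        label_of = {}
        for k, mod in enumerate(self.modules_):
            for g in mod.members:
                label_of[g] = k
        self.labels_ = np.array([label_of.get(g, -1) for g in self.gene_ids_])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def border_pool_(self) -> set[str]:
        """Union of border genes across all extracted modules."""
        pool: set[str] = set()
        for m in self.modules_:
            pool |= m.border_genes
        return pool

    @property
    def border_provenance_(self) -> dict[str, int]:
        """Border gene -> module_id it was extracted from."""
        prov: dict[str, int] = {}
        for m in self.modules_:
            for g in m.border_genes:
                prov.setdefault(g, m.module_id)
        return prov
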