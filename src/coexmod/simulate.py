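"""Synthetic data with the exact structure the extraction method assumes.

Three generators, all pure functions of (spec, seed):

* :func:`generate_expression` — planted co-expression modules whose
  members are affine transforms (shift, scale, shift-and-scale, with
  negative scale factors exercised) of a module base profile, plus
  Gaussian noise; uncorrelated background genes; two sample classes
  with mean shifts in a subset of genes.
* :func:`generate_toy_ontology` — a small Biological Process DAG with
  one subtree per planted module and annotations mirroring module
  membership, emitted as OBO + GAF text that round-trips through the
  ontology readers.
* :func:`generate_border_scenario` — an expression matrix engineered so
  that, at the extraction threshold, one module forms with a known
  core and designated low-degree border genes.  Profiles are built from
  an orthonormal basis so their sample correlations match a prescribed
  similarity matrix exactly.

These emulate the structural assumptions of the method, not microarray
platform noise (probe effects, background correction) or realistic GO
topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class SyntheticSpec:
    """Ground-truth layout of a synthetic expression study.

    Defaults describe a small two-module design: modules of 6 and 5
    genes against 20 unstructured background genes, 14 samples per
    class (mirroring a typical two-arm microarray comparison),
    noise-free affine module patterns, scale factors of magnitude 0.5-2
    with random sign, and class-mean shifts in 30% of background genes
    plus every planted module.
    """

    n_modules: int = 2
    module_sizes: tuple = (6, 5)
    n_background: int = 20
    n_samples_per_class: int = 14
    noise_sigma: float = 0.0
    scale_range: tuple = (0.5, 2.0)   # magnitude; sign drawn at random
    shift_range: tuple = (-2.0, 2.0)
    de_fraction: float = 0.3
    de_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        lo, hi = self.scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("scale_range must be a positive interval")


@dataclass
class GroundTruth:
    """Planted labels: module index per gene (-1 background), DE flags."""

    module_label: dict[str, int]
    de_genes: set[str]
    module_genes: dict[int, list[str]] = field(default_factory=dict)


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Planted-module expression matrix with two sample classes.

    Each module m has a base profile b ~ N(0, 1) over the samples; a
    member's profile is ``a * (b + d_m * disease) + c + noise`` with the
    scale a drawn from +/-[scale_range] and shift c from shift_range per
    gene, so noise-free members are exact affine transforms of each
    other (within-module similarity 1 under an affine-invariant
    measure).  The module-level class shift d_m keeps the affine
    relation intact while making every member differentially expressed.
    Background genes are i.i.d. N(0, 1); a de_fraction of them get a
    +/-de_shift class-mean offset.
    """
    rng = np.random.default_rng(spec.seed)
    n_s = 2 * spec.n_samples_per_class
    disease = np.r_[np.zeros(spec.n_samples_per_class),
                    np.ones(spec.n_samples_per_class)]
    gene_ids, rows = [], []
    module_label: dict[str, int] = {}
    de_genes: set[str] = set()
    module_genes: dict[int, list[str]] = {}

    for m in range(spec.n_modules):
        base = rng.normal(size=n_s)
        d_m = spec.de_shift if spec.de_fraction > 0 else 0.0
        shifted = base + d_m * disease
        members = []
        for k in range(spec.module_sizes[m]):
            gid = f"mod{m + 1}_g{k + 1}"
            a = rng.uniform(*spec.scale_range) * rng.choice([-1.0, 1.0])
            c = rng.uniform(*spec.shift_range)
            prof = a * shifted + c
            if spec.noise_sigma > 0:
                prof = prof + rng.normal(scale=spec.noise_sigma, size=n_s)
            gene_ids.append(gid)
            rows.append(prof)
            module_label[gid] = m
            members.append(gid)
            if d_m != 0.0:
                de_genes.add(gid)
        module_genes[m] = members

    n_de_bg = int(round(spec.de_fraction * spec.n_background))
    de_bg = set(rng.choice(spec.n_background, size=n_de_bg, replace=False)
                ) if n_de_bg else set()
    for k in range(spec.n_background):
        gid = f"bg_g{k + 1}"
        prof = rng.normal(size=n_s)
        if k in de_bg:
            prof = prof + rng.choice([-1.0, 1.0]) * spec.de_shift * disease
            de_genes.add(gid)
        gene_ids.append(gid)
        rows.append(prof)
        module_label[gid] = -1

    data = pd.DataFrame(np.asarray(rows), index=gene_ids,
                        columns=[f"s{i + 1}" for i in range(n_s)])
    classes = pd.Series(["normal"] * spec.n_samples_per_class
                        + ["disease"] * spec.n_samples_per_class,
                        index=data.columns, name="class")
    em = ExpressionMatrix(data=data, sample_class=classes)
    return em, GroundTruth(module_label=module_label, de_genes=de_genes,
                           module_genes=module_genes)


def planted_recovery_ari(gene_ids, labels, truth: GroundTruth) -> float:
    """Adjusted Rand index between extracted and planted partitions.

    Computed over the genes belonging to planted modules: background
    genes carry no planted co-expression structure, so whether random
    fluctuations leave them unassigned or grouped at a low threshold
    says nothing about module recovery.
    """
    from sklearn.metrics import adjusted_rand_score

    pairs = [(truth.module_label[g], lab)
             for g, lab in zip(gene_ids, labels)
             if truth.module_label[g] >= 0]
    true_l, got_l = zip(*pairs)
    return float(adjusted_rand_score(true_l, got_l))


ROOT_TERM = "GO:0000001"


def generate_toy_ontology(spec: SyntheticSpec) -> tuple[str, str]:
    """Toy BP ontology + annotations mirroring the planted modules.

    The DAG is a root with one subtree per module (a parent term with
    two leaf children).  Module members are annotated alternately to
    their subtree's leaves; background genes are annotated to the root.
    Returns (obo_text, gaf_text) in the dialects the readers consume.
    """
    terms = [(ROOT_TERM, "biological_process_root", None)]
    annotations: list[tuple[str, str]] = []
    for m in range(spec.n_modules):
        parent = f"GO:{m + 1:07d}0"
        leaves = [f"GO:{m + 1:07d}{k}" for k in (1, 2)]
        terms.append((parent, f"module{m + 1}_process", ROOT_TERM))
        for leaf in leaves:
            terms.append((leaf, f"module{m + 1}_subprocess_{leaf[-1]}", parent))
        for k in range(spec.module_sizes[m]):
            gid = f"mod{m + 1}_g{k + 1}"
            annotations.append((gid, leaves[k % 2]))
    for k in range(spec.n_background):
        annotations.append((f"bg_g{k + 1}", ROOT_TERM))

    return _obo_text(terms), _gaf_text(annotations)


def _obo_text(terms) -> str:
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for tid, name, parent in terms:
        lines += ["[Term]", f"id: {tid}", f"name: {name}",
                  "namespace: biological_process"]
        if parent:
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")
    return "\n".join(lines)


def _gaf_text(annotations) -> str:
    lines = ["!gaf-version: 2.1"]
    for gene, term in annotations:
        cols = ["SYN", gene, gene, "", term, "SYN:ref", "IEA", "", "P",
                gene, "", "gene", "taxon:0000", "20160101", "SYN", "", ""]
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def _orthonormal_centered_basis(n_vec: int, n_samples: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Rows: n_vec orthonormal vectors in R^n_samples, each orthogonal
    to the all-ones vector (i.e. mean-zero).  Needs n_samples >= n_vec + 1."""
    if n_samples < n_vec + 1:
        raise ValueError("need n_samples >= n_vec + 1")
    G = rng.normal(size=(n_samples, n_vec))
    G -= G.mean(axis=0, keepdims=True)  # project out the ones direction
    Q, _ = np.linalg.qr(G)
    return Q[:, :n_vec].T


def realize_correlations(target: np.ndarray, n_samples: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Profiles whose sample Pearson correlations equal ``target`` exactly.

    ``target`` must be a valid correlation matrix (symmetric, unit
    diagonal, positive semidefinite).  Rows of the result are linear
    combinations of mean-zero orthonormal basis vectors, so the Gram
    matrix of the centered profiles is exactly the Cholesky-factored
    target.
    """
    target = np.asarray(target, dtype=float)
    n = target.shape[0]
    w, V = np.linalg.eigh(target)
    if w.min() < -1e-10:
        raise ValueError(f"target correlation matrix not PSD (min eig {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)  # target == L @ L.T
    B = _orthonormal_centered_basis(n, n_samples, rng)
    return L @ B


def border_scenario_similarity(rho: int = 3):
    """Design the target similarity matrix of the border scenario.

    Genes: a hub, ``rho`` members forming a clique with the hub, and
    ``rho - 1`` border genes where border i has exactly i edges (to the
    first i members).  Edges target similarity 0.93, non-edges 0.80
    (correlation geometry forbids low non-edge values between
    neighbors of strongly correlated genes).  The target is projected
    to the nearest correlation matrix and the projection is verified to
    leave the designed 0.9-threshold graph intact — feasible for
    moderate rho (<= 4); larger rho raises ValueError.
    Returns (gene_ids, target matrix, expected roles dict).
    """
    if rho < 1:
        raise ValueError("rho must be >= 1")
    hub = "hub"
    members = [f"m{i + 1}" for i in range(rho)]
    borders = [f"b{i + 1}" for i in range(max(rho - 1, 0))]
    genes = [hub] + members + borders
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    S = np.full((n, n), 0.80)
    np.fill_diagonal(S, 1.0)

    def set_edge(a, b, v=0.93):
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = v

    for m in members:
        set_edge(hub, m)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            set_edge(a, b)
    for i, b in enumerate(borders, start=1):
        for m in members[:i]:
            set_edge(b, m)

    A0 = S >= 0.9
    np.fill_diagonal(A0, False)

    # project to the PSD cone and renormalize the diagonal; the designed
    # graph must survive thresholding at 0.9 with margin
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 1e-6, None)
    P = (V * w) @ V.T
    d = np.sqrt(np.diag(P))
    S = P / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    off = ~np.eye(n, dtype=bool)
    bad_edge = A0.any() and S[A0].min() < 0.905
    bad_nonedge = (off & ~A0).any() and S[off & ~A0].max() > 0.85
    if bad_edge or bad_nonedge:
        raise ValueError(f"rho={rho} too large for the designed border scenario")

    A = S >= 0.9
    np.fill_diagonal(A, False)
    deg = A.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-deg[i], genes[i]))
    roles = {}
    core = genes[order[0]]
    for i, g in enumerate(genes):
        if g == core:
            roles[g] = "core"
        elif deg[i] < rho:
            roles[g] = "border"
        else:
            roles[g] = "member"
    return genes, S, roles


@dataclass
class PrioritizationStudy:
    """A full synthetic study for the border-gene pipeline."""

    expression: ExpressionMatrix
    roles: dict[str, str]             # gene -> core/member/border/background
    obo_text: str
    gaf_text: str
    coherent_border: set[str]         # borders sharing a toy-GO subtree
    incoherent_border: set[str]       # borders annotated to the root only


def generate_prioritization_study(n_modules: int = 2, rho: int = 3,
                                  n_background: int = 8,
                                  n_samples: int = 28,
                                  de_scale: float = 3.0,
                                  seed: int = 0) -> PrioritizationStudy:
    """A study whose modules carry genuine border genes.

    Each module is a border scenario (hub + rho-member clique + rho-1
    low-degree border genes) realized on its own orthonormal subspace,
    so cross-module correlations are exactly zero; background genes are
    i.i.d. normal.  Border genes of module 1 are annotated coherently
    to one leaf of their toy-GO subtree; border genes of the other
    modules only to the root, so under the beta mean-threshold rule the
    module-1 borders are the expected interesting set.  Border genes'
    profiles are scaled by ``de_scale`` (scaling changes variance but
    not correlations), making them the top of the variance ranking.
    """
    rng = np.random.default_rng(seed)
    genes_b, S_b, roles_b = border_scenario_similarity(rho)
    k = len(genes_b)
    n_mod_genes = n_modules * k
    target = np.zeros((n_mod_genes, n_mod_genes))
    gene_ids, roles = [], {}
    for m in range(n_modules):
        sl = slice(m * k, (m + 1) * k)
        target[sl, sl] = S_b
        for g in genes_b:
            gid = f"mod{m + 1}_{g}"
            gene_ids.append(gid)
            roles[gid] = roles_b[g]
    X = realize_correlations(target, n_samples, rng) * np.sqrt(n_samples)
    rows = list(X)
    for j in range(n_background):
        gid = f"bg_g{j + 1}"
        gene_ids.append(gid)
        roles[gid] = "background"
        rows.append(rng.normal(size=n_samples))
    X = np.asarray(rows)
    border = [g for g in gene_ids if roles[g] == "border"]
    for g in border:
        X[gene_ids.index(g)] *= de_scale

    data = pd.DataFrame(X, index=gene_ids,
                        columns=[f"s{i + 1}" for i in range(n_samples)])
    half = n_samples // 2
    classes = pd.Series(["normal"] * half + ["disease"] * (n_samples - half),
                        index=data.columns, name="class")
    em = ExpressionMatrix(data=data, sample_class=classes)

    terms = [(ROOT_TERM, "biological_process_root", None)]
    annotations = []
    for m in range(n_modules):
        parent = f"GO:{m + 1:07d}0"
        leaves = [f"GO:{m + 1:07d}{i}" for i in (1, 2)]
        terms.append((parent, f"module{m + 1}_process", ROOT_TERM))
        for leaf in leaves:
            terms.append((leaf, f"module{m + 1}_subprocess_{leaf[-1]}", parent))
        for g in genes_b:
            gid = f"mod{m + 1}_{g}"
            if roles_b[g] == "border":
                # coherent annotations only in module 1
                annotations.append((gid, leaves[0] if m == 0 else ROOT_TERM))
            else:
                annotations.append((gid, leaves[1]))
    for j in range(n_background):
        annotations.append((f"bg_g{j + 1}", ROOT_TERM))

    coherent = {g for g in border if g.startswith("mod1_")}
    return PrioritizationStudy(
        expression=em, roles=roles, obo_text=_obo_text(terms),
        gaf_text=_gaf_text(annotations), coherent_border=coherent,
        incoherent_border=set(border) - coherent)


def generate_border_scenario(rho: int = 3, n_samples: int = 16,
                             seed: int = 0):
    """Expression matrix realizing the border scenario at delta = 0.9.

    Returns (ExpressionMatrix, expected_roles, delta).  Expected roles
    are derived from the designed adjacency (degrees known by
    construction), independently of the extractor.
    """
    genes, S, roles = border_scenario_similarity(rho)
    rng = np.random.default_rng(seed)
    X = realize_correlations(S, n_samples, rng)
    data = pd.DataFrame(X, index=genes,
                        columns=[f"s{i + 1}" for i in range(n_samples)])
    half = n_samples // 2
    classes = pd.Series(["normal"] * half + ["disease"] * (n_samples - half),
                        index=data.columns, name="class")
    em = ExpressionMatrix(data=data, sample_class=classes)
    return em, roles, 0.9
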