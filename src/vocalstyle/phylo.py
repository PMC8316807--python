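"""Time-calibrated phylogeny handling and phylogenetic GLS.

Trees are rooted, with branch lengths in Myr, parsed from Newick via
dendropy.  The species-level models are generalized least squares with the
residual covariance proportional to shared ancestry: C[i, j] is the depth
(from the root) of the most recent common ancestor of tips i and j, and
Pagel's λ multiplies the off-diagonal entries (λ = 1 assumes full Brownian
signal; λ = 0 recovers ordinary least squares).  λ is fixed, never
estimated: with ~20 species there is no power to estimate phylogenetic
signal, so the models deliberately assume the maximum.

A taxon missing from the reference tree can be grafted as a sister lineage
to a named tip at a stated divergence time (used for *Papio kindae*, sister
to *P. cynocephalus* at 1.99 Myr), preserving ultrametricity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .tables import GroupMeta, RepertoireRecord, ValidationError
from .dominance import SpeciesStyleIndex

DEFAULT_LOG_OFFSET = 1.0  # added to repertoire counts before log10


# ---------------------------------------------------------------------------
# Tree I/O and manipulation
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    Accepts a path or a literal Newick string.  Missing branch lengths and
    duplicate tip labels are errors.
    """
    text = None
    p = Path(str(path_or_string))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(path_or_string)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"Newick parse error: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValidationError("missing branch length in Newick input")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance
            for leaf in tree.leaf_node_iter()}


def tree_height(tree: dendropy.Tree) -> float:
    return max(tip_depths(tree).values())


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = list(tip_depths(tree).values())
    return max(depths) - min(depths) <= tol


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf
    raise ValidationError(f"tip {label!r} not found in tree")


def graft_taxon(tree: dendropy.Tree, new_tip: str, sister: str,
                divergence: float) -> dendropy.Tree:
    """Graft ``new_tip`` as sister to the tip ``sister``.

    A new node is inserted on the sister's terminal branch ``divergence``
    Myr before the tip and the new tip attached there with branch length
    ``divergence``, so an ultrametric input stays ultrametric.  The
    divergence may not exceed the sister's terminal branch length.
    """
    tree = tree.clone(depth=1)
    leaf = _find_leaf(tree, sister)
    terminal = leaf.edge.length
    if divergence > terminal:
        raise ValidationError(
            f"divergence {divergence} exceeds terminal branch of "
            f"{sister!r} ({terminal})")
    if new_tip in tip_labels(tree):
        raise ValidationError(f"tip {new_tip!r} already in tree")
    parent = leaf.parent_node
    parent.remove_child(leaf)
    joint = parent.new_child(edge_length=terminal - divergence)
    joint.add_child(leaf)
    leaf.edge.length = divergence
    taxon = tree.taxon_namespace.require_taxon(label=new_tip)
    joint.new_child(taxon=taxon, edge_length=divergence)
    return tree


def prune_taxon(tree: dendropy.Tree, tip: str) -> dendropy.Tree:
    """Remove one tip, suppressing the resulting unifurcation."""
    tree = tree.clone(depth=1)
    leaf = _find_leaf(tree, tip)
    tree.prune_subtree(leaf, suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# Phylogenetic covariance and PGLS
# ---------------------------------------------------------------------------

@dataclass
class PhyloCovariance:
    """Phylogenetic covariance for an ordered species subset.

    ``C[i, j]`` is the root-to-MRCA depth of species i and j (Myr), with
    off-diagonals scaled by Pagel's λ.  Diagonal entries equal each tip's
    root-to-tip depth.
    """

    species: list[str]
    C: np.ndarray
    lam: float


def phylo_covariance(tree: dendropy.Tree, species: Sequence[str],
                     lam: float = 1.0) -> PhyloCovariance:
    """Shared-ancestry covariance matrix over a species subset."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0, 1], got {lam}")
    present = set(tip_labels(tree))
    missing = [s for s in species if s not in present]
    if missing:
        raise ValidationError(f"species not in tree: {missing}")
    depths = tip_depths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in present}
    n = len(species)
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = species[j]
            # MRCA depth = (depth_a + depth_b - patristic distance) / 2
            d = pdm.patristic_distance(taxa[a], taxa[b])
            mrca = 0.5 * (depths[a] + depths[b] - d)
            C[i, j] = C[j, i] = lam * mrca
    return PhyloCovariance(species=list(species), C=C, lam=lam)


@dataclass
class PglsResult:
    """Coefficients, standard errors and t-tests from one PGLS fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    n: int
    df: int


def pgls_fit(y: np.ndarray, X: np.ndarray, cov: PhyloCovariance,
             names: Optional[Sequence[str]] = None) -> PglsResult:
    """Generalized least squares under the phylogenetic covariance.

    β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹y, computed by Cholesky whitening; σ̂² is the
    whitened residual mean square on n − p degrees of freedom; two-sided
    p-values come from the t distribution.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    C = cov.C
    n, p = X.shape
    if y.shape[0] != n or C.shape != (n, n):
        raise ValidationError("dimension mismatch between y, X and C")
    if n - p < 1:
        raise ValidationError("residual degrees of freedom < 1")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValidationError("phylogenetic covariance is singular") from None
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(Xw) < p:
        raise ValidationError("design matrix is rank deficient")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(XtX)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    if names is None:
        names = [f"x{j}" for j in range(p)]
    return PglsResult(names=list(names), beta=beta, se=se, t=t, p=pvals,
                      sigma2=sigma2, n=n, df=df)


# ---------------------------------------------------------------------------
# Species trait table
# ---------------------------------------------------------------------------

def species_table(indices: Sequence[SpeciesStyleIndex],
                  repertoires: Sequence[RepertoireRecord],
                  group_meta: Sequence[GroupMeta],
                  log_offset: float = DEFAULT_LOG_OFFSET,
                  log: Optional[list[str]] = None) -> pd.DataFrame:
    """Join composite index, mean group size and log10 repertoire counts.

    Species missing from any source are dropped (and logged); repertoire
    counts are log10(count + offset) transformed, matching how they enter
    the species-level models.  Raises on an empty join.
    """
    idx = {s.species_id: s for s in indices}
    rep = {r.species_id: r for r in repertoires}
    sizes: dict[str, list[int]] = {}
    for g in group_meta:
        sizes.setdefault(g.species_id, []).append(g.group_size)

    rows = []
    for sp in sorted(set(idx) | set(rep) | set(sizes)):
        missing = [name for name, src in
                   (("style index", idx), ("repertoire", rep), ("groups", sizes))
                   if sp not in src]
        if missing:
            if log is not None:
                log.append(f"species {sp} dropped from species table: "
                           f"no {', '.join(missing)}")
            continue
        s, r = idx[sp], rep[sp]
        rows.append({
            "species_id": sp,
            "composite": s.composite,
            "mean_dii": s.mean_dii,
            "mean_counter": s.mean_counter,
            "mean_intensity": s.mean_intensity,
            "group_size": float(np.mean(sizes[sp])),
            "total_calls": r.total_calls,
            "hierarchy_calls": r.hierarchy_calls,
            "log_total_calls": np.log10(r.total_calls + log_offset),
            "log_hierarchy_calls": np.log10(r.hierarchy_calls + log_offset),
        })
    if not rows:
        raise ValidationError("species table join is empty")
    return pd.DataFrame(rows).set_index("species_id")
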