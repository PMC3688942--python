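"""Phylogeny handling: Newick I/O, pruning, and the PGLS covariance structure.

Under Brownian-motion trait evolution the expected covariance between two
species equals the shared branch length from the root to their most recent
common ancestor.  Pagel's λ rescales the off-diagonal entries of that matrix,
interpolating between star-like independence (λ = 0) and the full Brownian
expectation (λ = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CovarianceMatrix",
    "read_newick",
    "parse_newick",
    "prune",
    "vcv",
    "lambda_transform",
    "normalize_label",
]


class PhylogenyError(ValueError):
    """Raised for malformed trees or label mismatches."""


def normalize_label(label: str) -> str:
    """Canonical species key: case-folded, underscores as spaces, trimmed."""
    return " ".join(label.replace("_", " ").split()).casefold()


@dataclass(frozen=True)
class Phylogeny:
    """A rooted, branch-length-annotated tree (thin dendropy wrapper)."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def write_newick(self, path: str | Path | None = None) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        if path is not None:
            Path(path).write_text(s)
        return s

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return (max(depths) - min(depths)) <= rel_tol * max(max(depths), 1e-12)


@dataclass(frozen=True)
class CovarianceMatrix:
    """Taxon-labelled among-species covariance with its λ multiplier."""

    taxa: tuple[str, ...]
    V: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "V", V)
        n = len(self.taxa)
        if V.shape != (n, n):
            raise ValueError("V must be square and match taxa")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("V must be symmetric")
        if np.any(np.diag(V) <= 0):
            raise ValueError("V diagonal must be positive")

    def reorder(self, taxa: Sequence[str]) -> "CovarianceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CovarianceMatrix(tuple(taxa), self.V[np.ix_(idx, idx)], self.lam)


# ---------------------------------------------------------------------------
# I/O and pruning
# ---------------------------------------------------------------------------


def _validate(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise PhylogenyError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise PhylogenyError(
                f"missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
        if edge.length < 0:
            raise PhylogenyError("negative branch length")


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths from a file."""
    return parse_newick(Path(path).read_text())


def parse_newick(newick: str) -> Phylogeny:
    """Parse a Newick string; branch lengths required, duplicate tips rejected."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Multiple occurrences" in msg or "uplicate" in msg:
            raise PhylogenyError(f"duplicate tip labels: {msg}") from exc
        raise PhylogenyError(f"invalid newick: {msg}") from exc
    _validate(tree)
    return Phylogeny(tree)


def prune(phy: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``; patristic distances among kept tips preserved.

    Degree-2 internal nodes left by the pruning are collapsed with their
    branch lengths summed (dendropy does this on extraction).
    """
    keep = list(keep)
    have = {normalize_label(l): l for l in phy.tip_labels}
    missing = [k for k in keep if normalize_label(k) not in have]
    if missing:
        raise PhylogenyError(f"species not in tree: {sorted(missing)}")
    wanted = {have[normalize_label(k)] for k in keep}
    sub = phy.tree.extract_tree_with_taxa_labels(labels=wanted)
    sub.purge_taxon_namespace()
    return Phylogeny(sub)


# ---------------------------------------------------------------------------
# covariance structure
# ---------------------------------------------------------------------------


def vcv(phy: Phylogeny) -> CovarianceMatrix:
    """Brownian-motion among-species covariance matrix.

    ``V[i, j]`` is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds root-to-tip depths.  Computed by accumulating each
    edge's length over the tip pairs that descend from it.
    """
    tree = phy.tree
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        node._tip_idx = (
            [index[id(node)]]
            if node.is_leaf()
            else [i for ch in node.child_nodes() for i in ch._tip_idx]
        )
        length = node.edge.length
        if node is tree.seed_node or not length:
            continue
        idx = np.array(node._tip_idx)
        V[np.ix_(idx, idx)] += length
    for node in tree.postorder_node_iter():
        del node._tip_idx
    return CovarianceMatrix(tuple(labels), V, lam=1.0)


def lambda_transform(cov: CovarianceMatrix, lam: float) -> CovarianceMatrix:
    """Multiply the off-diagonal covariances by Pagel's λ ∈ [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    return replace(cov, V=V, lam=lam * cov.lam)


def covariance_for(phy: Phylogeny, taxa: Sequence[str]) -> CovarianceMatrix:
    """Prune to ``taxa`` (matched after label normalization), build V, and
    return it row-ordered as ``taxa``.  Warns on non-ultrametric trees, whose
    unequal tip depths are kept as-is on the diagonal."""
    sub = prune(phy, taxa)
    if not sub.is_ultrametric():
        warnings.warn("tree is not ultrametric; tip depths kept on the diagonal")
    cov = vcv(sub)
    by_norm = {normalize_label(t): t for t in cov.taxa}
    ordered = [by_norm[normalize_label(t)] for t in taxa]
    cov = cov.reorder(ordered)
    return CovarianceMatrix(tuple(taxa), cov.V, cov.lam)
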