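"""Phylogenetic containers, patristic distances and the k-NN trait baseline.

The k-nearest-neighbour predictor estimates a species' (log) trait as the
unweighted mean of the trait values of its K patristically closest training
species. It serves both as the comparator baseline for the methylation
predictors and as the K=1 imputation engine for missing trait values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidTreeError, LeakageError


@dataclass
class Phylogeny:
    """A rooted tree over the species universe, plus optional order labels.

    ``tree`` is a dendropy Tree whose taxon labels are the species names;
    ``orders`` (if present) maps every species to a taxonomic-order label.
    """

    tree: dendropy.Tree
    orders: dict[str, str] | None = field(default=None)

    @property
    def species(self) -> list[str]:
        return sorted(t.taxon.label for t in self.tree.leaf_node_iter())

    def write_newick(self, path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)

    @classmethod
    def read_newick(cls, path, orders: dict[str, str] | None = None) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree=tree, orders=orders)

    def patristic_distances(self) -> pd.DataFrame:
        return tree_distances(self)


def tree_distances(phylo: Phylogeny) -> pd.DataFrame:
    """Patristic distance matrix: path length between every pair of tips.

    Raises
    ------
    InvalidTreeError
        If any non-root edge lacks a branch length.
    """
    tree = phylo.tree
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise InvalidTreeError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n), dtype=float)
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if j <= i:
                continue
            d = pdm.patristic_distance(ti, tj)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def knn_predict(
    distances: pd.DataFrame,
    y: pd.Series,
    targets,
    k: int = 1,
) -> pd.Series:
    """Predict targets' trait as the mean of their K nearest training species.

    Parameters
    ----------
    distances
        Symmetric species x species patristic distance matrix covering
        both training species and targets.
    y
        Log-trait values indexed by training species. The training set
        must not contain any target (that would be leakage).
    targets
        Species to predict.
    k
        Number of neighbours; distance ties are broken by lexicographic
        species name so predictions are deterministic.
    """
    targets = list(targets)
    train = list(y.index)
    if len(train) == 0:
        raise InvalidArgumentError("empty training set")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > len(train):
        raise InvalidArgumentError(f"k={k} exceeds training set size {len(train)}")
    overlap = set(targets) & set(train)
    if overlap:
        raise LeakageError(f"targets present in training set: {sorted(overlap)}")
    missing = [s for s in targets + train if s not in distances.index]
    if missing:
        raise InvalidArgumentError(f"species missing from distance matrix: {missing}")

    preds = {}
    for t in targets:
        row = distances.loc[t, train]
        ranked = sorted(zip(row.to_numpy(dtype=float), train))
        nearest = [name for _, name in ranked[:k]]
        preds[t] = float(y.loc[nearest].mean())
    return pd.Series(preds, index=targets, name="predicted")


def knn_cv(distances: pd.DataFrame, y: pd.Series, folds, k: int = 1):
    """Run the k-NN predictor over externally supplied CV folds.

    ``folds`` is an iterable of ``(fold_id, train_species, test_species)``
    triples (as produced by :func:`methylspan.model.loso_folds` and
    :func:`methylspan.model.loco_folds`), so the baseline is evaluated on
    exactly the same splits as the methylation predictor.
    """
    from .containers import CVResult

    rows = []
    for fold_id, train, test in folds:
        pred = knn_predict(distances, y.loc[list(train)], list(test), k=k)
        for sp in test:
            rows.append(
                {
                    "stratum": sp,
                    "species": sp,
                    "fold": fold_id,
                    "observed": float(y.loc[sp]),
                    "predicted": float(pred.loc[sp]),
                }
            )
    table = pd.DataFrame(rows).set_index("stratum")
    return CVResult(table=table, scheme=f"knn_k{k}")
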