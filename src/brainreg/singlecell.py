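"""Cluster label transfer and per-cluster cross-species DEG calling.

Cross-species integration and clustering are upstream inputs: cells arrive
with cluster assignments, and the comparator primate's cells carry
reference cell-type labels. Each integrated cluster is annotated as the
reference cell type with the largest percentage among its reference-species
cells. Within each cluster, genes are tested between species with the
two-sided Wilcoxon rank-sum test, adjusted across genes within the
(cluster, species pair) stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConsistencyError, InputError
from .expression import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class CellTable:
    """Gene x cell expression with per-cell metadata.

    ``expression``: DataFrame genes x cell_ids (non-negative).
    ``cell_meta``: DataFrame indexed by cell_id with columns species,
    cluster_id and optional reference_label.
    """

    expression: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self):
        if list(self.expression.columns) != list(self.cell_meta.index):
            raise ConsistencyError(
                "expression columns and cell metadata ids differ")
        for col in ("species", "cluster_id"):
            if col not in self.cell_meta.columns:
                raise ConsistencyError(f"cell metadata lacks {col!r}")
        if (self.expression.to_numpy() < 0).any():
            raise ConsistencyError("negative expression values")


def transfer_cluster_labels(cells: CellTable,
                            reference_species: str) -> pd.DataFrame:
    """Annotate each cluster by its majority reference cell type.

    Per cluster the label is the reference species' cell type with the
    largest percentage among that cluster's reference cells; exact ties go
    to the lexicographically smaller label and are flagged. Clusters with
    no reference cells are 'unassigned'.
    """
    meta = cells.cell_meta
    if "reference_label" not in meta.columns:
        raise InputError("cell metadata lacks reference_label")
    rows = []
    for cluster, sub in meta.groupby("cluster_id"):
        ref = sub[sub["species"] == reference_species]
        ref = ref[ref["reference_label"].notna()]
        if len(ref) == 0:
            rows.append({"cluster_id": cluster, "label": "unassigned",
                         "fraction": np.nan, "tie": False})
            continue
        frac = (ref["reference_label"].value_counts() / len(ref))
        top = frac.max()
        winners = sorted(frac.index[frac == top])
        rows.append({"cluster_id": cluster, "label": winners[0],
                     "fraction": float(top), "tie": len(winners) > 1})
    return pd.DataFrame(rows).set_index("cluster_id")


def per_cluster_species_deg(cells: CellTable, species_a: str,
                            species_b: str, alpha: float = 0.05,
                            adjust: str = "bonferroni",
                            min_cells: int = 3) -> pd.DataFrame:
    """Wilcoxon rank-sum DEGs between two species within each cluster.

    Two-sided test per gene (midranks with normal approximation and
    continuity correction under ties); adjustment across genes within each
    (cluster, pair) stratum, Bonferroni by default with BH selectable.
    Genes are reported iff adjusted p < ``alpha``. Clusters with fewer than
    ``min_cells`` cells in either species are skipped with a warning.
    Direction is the sign of the mean difference (a minus b); log2fc uses
    pseudocount 1. Constant genes (all ties) get p = 1 by convention.
    """
    if adjust not in ("bonferroni", "bh"):
        raise InputError(f"unknown adjustment {adjust!r}")
    meta = cells.cell_meta
    expr = cells.expression
    out = []
    for cluster, sub in meta.groupby("cluster_id"):
        a_cells = sub.index[sub["species"] == species_a]
        b_cells = sub.index[sub["species"] == species_b]
        if len(a_cells) < min_cells or len(b_cells) < min_cells:
            log.warning("cluster %s skipped: %d vs %d cells", cluster,
                        len(a_cells), len(b_cells))
            continue
        A = expr[a_cells].to_numpy(dtype=float)
        B = expr[b_cells].to_numpy(dtype=float)
        constant = np.array([np.unique(np.concatenate([a, b])).size <= 1
                             for a, b in zip(A, B)])
        p = np.ones(len(expr))
        if (~constant).any():
            res = stats.mannwhitneyu(A[~constant], B[~constant], axis=1,
                                     alternative="two-sided",
                                     method="asymptotic")
            p[~constant] = res.pvalue
        p = np.where(np.isfinite(p), p, 1.0)
        if adjust == "bonferroni":
            p_adj = np.minimum(p * len(p), 1.0)
        else:
            p_adj = bh_adjust(p)
        mean_diff = A.mean(axis=1) - B.mean(axis=1)
        lfc = np.log2(A.mean(axis=1) + 1) - np.log2(B.mean(axis=1) + 1)
        sig = p_adj < alpha
        for g, lf, pv, pa, d in zip(expr.index[sig], lfc[sig], p[sig],
                                    p_adj[sig], mean_diff[sig]):
            out.append({"cluster_id": cluster, "gene_id": g,
                        "log2fc": float(lf), "p": float(pv),
                        "p_adj": float(pa),
                        "direction": "up" if d > 0 else "down"})
    return pd.DataFrame(out, columns=["cluster_id", "gene_id", "log2fc",
                                      "p", "p_adj", "direction"])


def regulatory_fraction(degs, element_linked_genes: dict) -> pd.DataFrame:
    """Fraction of DEGs linked to regulatory elements of each class.

    fraction = |degs ∩ linked(class)| / |degs|, per class, with counts.
    Undefined (NaN, applicable=False) when the DEG set is empty.
    """
    degs = set(degs)
    rows = []
    for cls, linked in element_linked_genes.items():
        n_overlap = len(degs & set(linked))
        rows.append({"class": cls, "n_degs": len(degs),
                     "n_linked": n_overlap,
                     "fraction": n_overlap / len(degs) if degs else np.nan,
                     "applicable": bool(degs)})
    return pd.DataFrame(rows).set_index("class")
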