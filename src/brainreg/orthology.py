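"""Cross-species gene anchoring, promoter windows, element-to-gene linkage.

Promoter windows follow the convention of 2 kb upstream plus 1 kb
downstream of the TSS, strand-aware and clipped at the chromosome start.
Elements (e.g. rapidly evolving conserved noncoding elements) are linked to
genes by edge-to-edge distance to the gene body within a 500 kb window,
either to the nearest gene or to all genes within the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import GeneAnnotation, IntervalSet, OrthologMap


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int
    end: int


def promoter_window(gene, upstream_bp: int = 2000,
                    downstream_bp: int = 1000) -> PromoterWindow:
    """Strand-aware promoter window around a gene's TSS, clipped at 0.

    On '+' the window is [tss - upstream, tss + downstream); on '-' it is
    the genomic mirror [tss - downstream + 1, tss + upstream + 1), so the
    TSS base plus ``downstream_bp - 1`` transcribed bases and
    ``upstream_bp`` upstream bases are covered on either strand.
    """
    strand = gene["strand"]
    if strand not in ("+", "-"):
        raise InputError(f"gene {gene['gene_id']!r} has no valid strand")
    tss = int(gene["tss"]) if "tss" in gene else (
        int(gene["start"]) if strand == "+" else int(gene["end"]) - 1)
    if strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp
    else:
        start, end = tss - downstream_bp + 1, tss + upstream_bp + 1
    return PromoterWindow(gene["gene_id"], gene["chrom"], max(0, start), end)


def promoter_windows(genes: GeneAnnotation, upstream_bp: int = 2000,
                     downstream_bp: int = 1000) -> IntervalSet:
    """Promoter windows for every gene, as an IntervalSet named by gene_id."""
    rows = [promoter_window(g, upstream_bp, downstream_bp)
            for _, g in genes.df.iterrows()]
    return IntervalSet(pd.DataFrame(
        {"chrom": [w.chrom for w in rows], "start": [w.start for w in rows],
         "end": [w.end for w in rows], "name": [w.gene_id for w in rows]}))


def _gap(e_start, e_end, g_start, g_end):
    """Edge-to-edge distance between half-open intervals; 0 on overlap."""
    return max(g_start - e_end, e_start - g_end, 0)


def link_elements_to_genes(elements: IntervalSet, genes: GeneAnnotation,
                           window_bp: int = 500_000,
                           mode: str = "nearest") -> pd.DataFrame:
    """Link each element to the nearest gene body (or all genes) within
    ``window_bp``.

    Distance is edge-to-edge to the gene BODY (0 when overlapping).
    ``mode='nearest'`` returns at most one link per element, ties broken by
    lexicographically smaller gene_id; ``mode='all_within'`` returns every
    gene within the window. Elements with no gene in range yield no link.
    """
    if mode not in ("nearest", "all_within"):
        raise InputError(f"unknown linkage mode {mode!r}")
    gdf = genes.df
    by_chrom = {c: sub for c, sub in gdf.groupby("chrom")}
    out = []
    for _, el in elements.df.iterrows():
        sub = by_chrom.get(el["chrom"])
        if sub is None:
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        dist = np.maximum(np.maximum(gs - el["end"], el["start"] - ge), 0)
        within = dist <= window_bp
        if not within.any():
            continue
        if mode == "all_within":
            for gid, d in zip(sub["gene_id"].to_numpy()[within],
                              dist[within]):
                out.append({"element_id": el["name"], "gene_id": gid,
                            "distance": int(d), "mode": mode})
        else:
            dmin = dist[within].min()
            cands = sorted(sub["gene_id"].to_numpy()[within & (dist == dmin)])
            out.append({"element_id": el["name"], "gene_id": cands[0],
                        "distance": int(dmin), "mode": mode})
    return pd.DataFrame(out, columns=["element_id", "gene_id", "distance",
                                      "mode"])


def project_gene_sets(omap: OrthologMap, gene_set, from_species: str,
                      to_species: str):
    """Translate a gene set between species via one-to-one orthologs.

    Genes without an ortholog row are dropped; the dropped count is
    returned alongside the translated set (and reported as a warning).
    """
    translated, n_dropped = omap.translate(gene_set, from_species, to_species)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} gene(s) of {from_species} without {to_species} "
            "ortholog dropped", stacklevel=2)
    return translated, n_dropped
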