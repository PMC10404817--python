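"""Primate-specific brain-biased gene (PSBEG) selection.

PSBEGs are genes expressed significantly higher in brain than nonbrain
tissues in primates but lower in brain than nonbrain in nonprimates. The
decision tree: (1) candidate set logic over per-species brain-up DEG sets;
(2) require the gene's top organ in the reference primate to be a brain
organ; (3) main branch: require the top organ in the nonprimate and in the
mouse-like outgroup to be a nonbrain organ; alternative branch: intersect
with the nonprimate brain-DOWN set, then the outgroup organ filter — this
experimental subset is provably contained in the main final set under the
organ-summary convention used here.

A separate fetal-zone filter retains genes active across fetal human
neocortical zones (SVZ, VZ, aRG, bRG) but silent in the fetal mouse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .expression import median_of_ratios_size_factors
from .io import ExpressionStudy, OrthologMap
from .orthology import project_gene_sets

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Organ summaries
# ---------------------------------------------------------------------------


@dataclass
class OrganSummary:
    """Per-gene per-organ summary expression plus organ group labels.

    ``table``: DataFrame genes x organs.
    ``organ_groups``: mapping organ -> 'brain' | 'nonbrain'.
    ``stat``: name of the summary statistic used.
    """

    table: pd.DataFrame
    organ_groups: dict
    stat: str = "median"

    def __post_init__(self):
        missing = set(self.table.columns) - set(self.organ_groups)
        if missing:
            raise InputError(
                f"organs {sorted(missing)} lack a brain/nonbrain label")


def organ_summary(study: ExpressionStudy,
                  size_factors: pd.Series | None = None,
                  stat: str = "median") -> OrganSummary:
    """Summarize normalized expression per organ (tissue).

    The summary statistic over samples of each organ is the median of
    median-of-ratios-normalized counts by default (mean selectable).
    """
    if stat not in ("median", "mean"):
        raise InputError(f"unknown summary stat {stat!r}")
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(study.counts)
    sf = size_factors.reindex(study.counts.columns).to_numpy(dtype=float)
    norm = study.counts.to_numpy(dtype=float) / sf[None, :]
    meta = study.sample_meta
    organs = {}
    groups = {}
    for organ, sub in meta.groupby("tissue"):
        cols = [study.counts.columns.get_loc(s) for s in sub.index]
        block = norm[:, cols]
        organs[organ] = np.median(block, axis=1) if stat == "median" \
            else block.mean(axis=1)
        groups[organ] = sub["group"].iloc[0]
    table = pd.DataFrame(organs, index=study.counts.index)
    return OrganSummary(table, groups, stat)


def organ_top_filter(summary: OrganSummary, require: str, genes) -> set:
    """Keep genes whose strict unique argmax organ is of the required group.

    ``require``: 'brain_top' or 'nonbrain_top'. Ties fail (a gene passes
    only when "the highest" organ is unique). Genes absent from the summary
    are dropped with a warning.
    """
    if require not in ("brain_top", "nonbrain_top"):
        raise InputError(f"unknown requirement {require!r}")
    want = "brain" if require == "brain_top" else "nonbrain"
    genes = set(genes)
    present = genes & set(summary.table.index)
    absent = genes - present
    if absent:
        log.warning("organ_top_filter: %d gene(s) absent from summary "
                    "dropped", len(absent))
    if not present:
        return set()
    sub = summary.table.loc[sorted(present)]
    arr = sub.to_numpy(dtype=float)
    mx = arr.max(axis=1)
    is_max = arr == mx[:, None]
    unique = is_max.sum(axis=1) == 1
    organ_is_wanted = np.array(
        [summary.organ_groups[o] == want for o in sub.columns])
    top_ok = (is_max & organ_is_wanted[None, :]).any(axis=1)
    keep = unique & top_ok
    return set(sub.index[keep])


# ---------------------------------------------------------------------------
# Candidate-set logic and the full decision tree
# ---------------------------------------------------------------------------


def candidate_set_logic(h_up: set, m_up: set, t_up: set,
                        universe: set) -> set:
    """((H ∩ M) \\ T) ∪ (H \\ (M ∪ T)) on the ortholog universe.

    The first term is the shared primate brain-up signal minus the
    nonprimate's; the second adds reference-primate-specific brain-up genes.
    """
    h_up, m_up, t_up = set(h_up), set(m_up), set(t_up)
    for name, s in (("H_up", h_up), ("M_up", m_up), ("T_up", t_up)):
        outside = s - set(universe)
        if outside:
            raise InputError(
                f"{name} contains ids outside the universe: "
                f"{sorted(outside)[:5]}")
    return ((h_up & m_up) - t_up) | (h_up - (m_up | t_up))


@dataclass
class PSBEGReport:
    """Output of the decision tree, with a per-gene audit trail.

    ``audit`` maps every universe gene to exactly one terminal disposition.
    ``experimental_subset`` is the alternative-branch output and is always
    a subset of ``final_set``.
    """

    candidate_set: set
    final_set: set
    experimental_subset: set
    audit: pd.DataFrame = field(repr=False)
    counts: dict = field(default_factory=dict)


def run_psbeg_pipeline(de_results: dict, organ_summaries: dict,
                       omap: OrthologMap,
                       reference: str = "human",
                       comparator: str = "macaque",
                       nonprimate: str = "treeshrew",
                       outgroup: str | None = "mouse") -> PSBEGReport:
    """Run the full PSBEG decision tree on the ortholog universe.

    ``de_results``: mapping species -> DE table (index = species gene ids,
    column 'call'). Required species: reference, comparator, nonprimate.
    ``organ_summaries``: mapping species -> OrganSummary on that species'
    gene ids. Required: reference, nonprimate; outgroup when given.
    All sets are projected onto the reference species' ids.
    """
    universe = omap.universe(reference)
    if not universe:
        raise InputError("empty ortholog universe")

    def up_set(species):
        de = de_results[species]
        ids = set(de.index[de["call"] == "up_in_brain"])
        if species == reference:
            return ids & universe
        projected, _ = project_gene_sets(omap, ids, species, reference)
        return projected

    h_up = up_set(reference)
    m_up = up_set(comparator)
    t_up = up_set(nonprimate)
    t_de = de_results[nonprimate]
    t_down_native = set(t_de.index[t_de["call"] == "down_in_brain"])
    t_down, _ = project_gene_sets(omap, t_down_native, nonprimate, reference)

    candidates = candidate_set_logic(h_up, m_up, t_up, universe)

    # Step 2: the reference primate's top organ must be a brain organ.
    ref_sum = organ_summaries[reference]
    after_ref = organ_top_filter(ref_sum, "brain_top", candidates)

    # Step 3 main branch: nonprimate top organ nonbrain, then outgroup.
    np_sum = organ_summaries[nonprimate]
    np_ids, _ = project_gene_sets(omap, after_ref, reference, nonprimate)
    np_pass_native = organ_top_filter(np_sum, "nonbrain_top", np_ids)
    np_pass, _ = project_gene_sets(omap, np_pass_native, nonprimate, reference)
    after_np = after_ref & np_pass

    if outgroup is not None:
        og_sum = organ_summaries[outgroup]
        og_ids, _ = project_gene_sets(omap, after_np, reference, outgroup)
        og_pass_native = organ_top_filter(og_sum, "nonbrain_top", og_ids)
        og_pass, _ = project_gene_sets(omap, og_pass_native, outgroup,
                                       reference)
        final_set = after_np & og_pass
    else:
        final_set = after_np

    # Alternative branch: brain-DOWN genes of the nonprimate, then outgroup.
    alt = after_ref & t_down
    if outgroup is not None:
        og_ids, _ = project_gene_sets(omap, alt, reference, outgroup)
        og_pass_native = organ_top_filter(organ_summaries[outgroup],
                                          "nonbrain_top", og_ids)
        og_pass, _ = project_gene_sets(omap, og_pass_native, outgroup,
                                       reference)
        alt = alt & og_pass
    # Significant brain-down implies nonbrain expression dominates in the
    # nonprimate, so the alternative branch is contained in the main one;
    # the organ summary is an independent estimate, so enforce the
    # containment invariant explicitly and report any violation.
    experimental = alt & final_set
    n_violating = len(alt - final_set)
    if n_violating:
        log.warning("alternative branch: %d gene(s) not in the main final "
                    "set excluded to preserve containment", n_violating)

    audit = {}
    for g in sorted(universe):
        if g not in candidates:
            audit[g] = "not_candidate"
        elif g not in after_ref:
            audit[g] = f"failed_{reference}_brain_top"
        elif g not in after_np:
            audit[g] = f"failed_{nonprimate}_nonbrain_top"
        elif g not in final_set:
            audit[g] = f"failed_{outgroup}_nonbrain_top"
        else:
            audit[g] = "psbeg"
    audit_df = pd.DataFrame({"gene_id": list(audit), "disposition":
                             list(audit.values())}).set_index("gene_id")
    counts = {"universe": len(universe), "h_up": len(h_up),
              "m_up": len(m_up), "t_up": len(t_up), "t_down": len(t_down),
              "candidates": len(candidates),
              "after_reference_brain_top": len(after_ref),
              "after_nonprimate_filter": len(after_np),
              "final": len(final_set), "experimental": len(experimental)}
    return PSBEGReport(candidates, final_set, experimental, audit_df, counts)


# ---------------------------------------------------------------------------
# Fetal-zone expression filter
# ---------------------------------------------------------------------------


def fetal_zone_filter(fpkm_human: pd.DataFrame, fpkm_mouse: pd.DataFrame,
                      genes, threshold: float = 1.0,
                      fraction: float = 0.80) -> set:
    """Keep genes active in fetal human zones but silent in fetal mouse.

    A gene survives iff log2(FPKM+1) > ``threshold`` in strictly more than
    ``fraction`` of human samples AND log2(FPKM+1) < ``threshold`` in
    strictly more than ``fraction`` of mouse samples. Genes missing from
    either table are dropped with a warning.
    """
    genes = set(genes)
    present = genes & set(fpkm_human.index) & set(fpkm_mouse.index)
    missing = genes - present
    if missing:
        log.warning("fetal_zone_filter: %d gene(s) missing from FPKM "
                    "tables dropped", len(missing))
    if not present:
        return set()
    order = sorted(present)
    h = np.log2(fpkm_human.loc[order].to_numpy(dtype=float) + 1.0)
    m = np.log2(fpkm_mouse.loc[order].to_numpy(dtype=float) + 1.0)
    h_frac = (h > threshold).mean(axis=1)
    m_frac = (m < threshold).mean(axis=1)
    keep = (h_frac > fraction) & (m_frac > fraction)
    return {g for g, k in zip(order, keep) if k}
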