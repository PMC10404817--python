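"""Cross-species epigenetic peak comparison and regulatory assignment.

A reference-species peak is carried to each comparator assembly through a
block coordinate map (a liftover-style conversion). Failure to convert, or
conversion onto a location with no overlapping peak in that species, both
count as "absent": a peak absent everywhere else is reference-specific
(human-specific), one shared with the comparator primate but absent in the
outgroup is primate-specific, and anything overlapping the outgroup is
shared.

Also here: the focal-gene regulatory scan (peaks within a +/-2 Mb flank of
a gene), promoter-anchored loop assignment, and the per-column conservation
profile (coverage x similarity) used to date element origins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ConfigurationError, InputError
from .io import BlockCoordinateMap, GeneAnnotation, IntervalSet, LoopSet

PEAK_CLASSES = ("human_specific", "primate_specific", "human_all_shared")


# ---------------------------------------------------------------------------
# Overlap index
# ---------------------------------------------------------------------------


class _OverlapIndex:
    """Per-chromosome interval tree over an IntervalSet (>=1 bp overlap)."""

    def __init__(self, ivset: IntervalSet):
        self.trees: dict[str, IntervalTree] = {}
        for chrom, sub in ivset.df.groupby("chrom"):
            self.trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], sub["name"]))

    def overlaps(self, chrom, start, end) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def hits(self, chrom, start, end) -> list:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


# ---------------------------------------------------------------------------
# Coordinate conversion and presence
# ---------------------------------------------------------------------------


def map_interval(interval, bmap: BlockCoordinateMap,
                 min_mapped_fraction: float = 0.95):
    """Convert (chrom, start, end) through a block map.

    Returns the target (chrom, start, end) span, or None when unmappable
    (mapped fraction below threshold, or blocks landing on different
    target chromosomes/orientations).
    """
    chrom, start, end = interval[0], int(interval[1]), int(interval[2])
    return bmap.map_interval(chrom, start, end, min_mapped_fraction)


def presence_verdict(interval, peaks_by_sample: Mapping,
                     rule="all_samples") -> str:
    """'present' or 'absent' across replicate peak sets.

    ``rule``: 'all_samples' (>=1 bp overlap with a peak in EVERY sample —
    the strict reading of presence across replicates), 'any_sample', or a
    float fraction f in (0, 1] requiring overlap in at least a fraction f
    of the samples.
    """
    if len(peaks_by_sample) == 0:
        raise InputError("presence_verdict needs at least one sample")
    chrom, start, end = interval[0], int(interval[1]), int(interval[2])
    hits = 0
    for sample, peaks in peaks_by_sample.items():
        idx = peaks if isinstance(peaks, _OverlapIndex) else _OverlapIndex(peaks)
        if idx.overlaps(chrom, start, end):
            hits += 1
    n = len(peaks_by_sample)
    if rule == "all_samples":
        ok = hits == n
    elif rule == "any_sample":
        ok = hits >= 1
    elif isinstance(rule, float) or (isinstance(rule, tuple) and
                                     rule[0] == "fraction"):
        f = rule if isinstance(rule, float) else rule[1]
        if not 0 < f <= 1:
            raise InputError(f"fraction rule must be in (0, 1], got {f}")
        ok = hits / n >= f
    else:
        raise InputError(f"unknown presence rule {rule!r}")
    return "present" if ok else "absent"


def _prebuild(species_samples: Mapping) -> dict:
    """Build overlap indices once per (species, sample)."""
    out = {}
    for species, samples in species_samples.items():
        out[species] = {s: _OverlapIndex(p) if not isinstance(p, _OverlapIndex)
                        else p for s, p in samples.items()}
    return out


def classify_cross_species_peaks(reference_peaks: IntervalSet,
                                 species_samples: Mapping,
                                 maps: Mapping,
                                 reference: str = "human",
                                 comparator: str = "macaque",
                                 outgroup: str = "mouse",
                                 rule="all_samples",
                                 min_mapped_fraction: float = 0.95
                                 ) -> pd.DataFrame:
    """Classify reference peaks as human_specific / primate_specific /
    human_all_shared from cross-species presence evidence.

    Evidence per non-reference species: 'unmappable' when conversion fails,
    else the presence verdict at the converted location. Unmappable counts
    as absent (a failed conversion is treated as loss of the element).
    human_specific: absent in comparator AND outgroup; primate_specific:
    present in comparator, absent in outgroup; human_all_shared: present in
    the outgroup. Peaks not present across the reference's own samples are
    left unclassified (class = NA).
    """
    for sp in (comparator, outgroup):
        if sp not in maps:
            raise ConfigurationError(f"no coordinate map for species {sp!r}")
        if sp not in species_samples:
            raise ConfigurationError(f"no sample peaks for species {sp!r}")
    idx = _prebuild(species_samples)
    ref_idx = idx.get(reference)
    rows = []
    for _, peak in reference_peaks.df.iterrows():
        iv = (peak["chrom"], peak["start"], peak["end"])
        if ref_idx is not None:
            ref_v = presence_verdict(iv, ref_idx, rule)
        else:
            ref_v = "present"
        evidence = {reference: ref_v}
        if ref_v != "present":
            rows.append({"name": peak["name"], "chrom": iv[0],
                         "start": iv[1], "end": iv[2], "class": pd.NA,
                         **{f"evidence_{s}": evidence.get(s, pd.NA)
                            for s in (reference, comparator, outgroup)}})
            continue
        for sp in (comparator, outgroup):
            mapped = map_interval(iv, maps[sp], min_mapped_fraction)
            if mapped is None:
                evidence[sp] = "unmappable"
            else:
                evidence[sp] = presence_verdict(mapped, idx[sp], rule)
        comp_absent = evidence[comparator] != "present"
        out_absent = evidence[outgroup] != "present"
        if comp_absent and out_absent:
            cls = "human_specific"
        elif not comp_absent and out_absent:
            cls = "primate_specific"
        else:
            cls = "human_all_shared"
        rows.append({"name": peak["name"], "chrom": iv[0], "start": iv[1],
                     "end": iv[2], "class": cls,
                     **{f"evidence_{s}": evidence[s]
                        for s in (reference, comparator, outgroup)}})
    return pd.DataFrame(rows).set_index("name")


def focal_gene_regulatory_scan(gene, reference_peaks: IntervalSet,
                               outgroup_samples: Mapping,
                               bmap: BlockCoordinateMap,
                               flank_bp: int = 2_000_000,
                               rule="all_samples",
                               min_mapped_fraction: float = 0.95
                               ) -> IntervalSet:
    """Reference peaks near a focal gene that are specifically activated
    relative to the outgroup.

    Peaks intersecting [gene_start - flank, gene_end + flank] are converted
    to the outgroup assembly; peaks that fail to convert OR convert without
    overlapping any outgroup peak are returned.
    """
    lo = max(0, int(gene["start"]) - flank_bp)
    hi = int(gene["end"]) + flank_bp
    chrom = gene["chrom"]
    idx = {s: _OverlapIndex(p) if not isinstance(p, _OverlapIndex) else p
           for s, p in outgroup_samples.items()}
    df = reference_peaks.df
    window = df[(df["chrom"] == chrom) & (df["start"] < hi) &
                (df["end"] > lo)]
    keep = []
    for _, peak in window.iterrows():
        iv = (peak["chrom"], peak["start"], peak["end"])
        mapped = map_interval(iv, bmap, min_mapped_fraction)
        if mapped is None or presence_verdict(mapped, idx, rule) == "absent":
            keep.append(peak)
    if not keep:
        return IntervalSet(pd.DataFrame(
            {"chrom": [], "start": [], "end": [], "name": []}))
    return IntervalSet(pd.DataFrame(keep).reset_index(drop=True))


# ---------------------------------------------------------------------------
# Loop-to-promoter assignment
# ---------------------------------------------------------------------------


def assign_loops_to_promoters(loops: LoopSet, promoters: IntervalSet,
                              elements: IntervalSet) -> pd.DataFrame:
    """Assign candidate elements to genes via promoter-anchored loops.

    For each loop with one anchor overlapping a gene's promoter window,
    elements overlapping the OTHER anchor are assigned to that gene
    (route 'loop_distal'). Elements overlapping a promoter window directly
    are assigned with route 'promoter_overlap'. Both routes may fire for
    the same element; all assignments are reported.
    """
    prom_idx = _OverlapIndex(promoters)
    elem_idx = _OverlapIndex(elements)
    rows = []
    for _, el in elements.df.iterrows():
        for gid in prom_idx.hits(el["chrom"], el["start"], el["end"]):
            rows.append({"gene_id": gid, "element_id": el["name"],
                         "route": "promoter_overlap", "loop_id": pd.NA})
    for _, loop in loops.df.iterrows():
        anchors = [(loop["chromA"], loop["startA"], loop["endA"]),
                   (loop["chromB"], loop["startB"], loop["endB"])]
        for a, b in ((0, 1), (1, 0)):
            genes = prom_idx.hits(*anchors[a])
            if not genes:
                continue
            hit_elements = elem_idx.hits(*anchors[b])
            for gid in genes:
                for eid in hit_elements:
                    rows.append({"gene_id": gid, "element_id": eid,
                                 "route": "loop_distal",
                                 "loop_id": loop["loop_id"]})
    out = pd.DataFrame(rows, columns=["gene_id", "element_id", "route",
                                      "loop_id"])
    return out.drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Conservation profile
# ---------------------------------------------------------------------------


def conservation_profile(alignment, reference_row: int = 0,
                         gap_chars: str = "-.") -> pd.DataFrame:
    """Per-column conservation score of a multiple alignment.

    coverage = fraction of rows with a residue; similarity = fraction of
    covered rows whose residue matches the reference row's (the reference
    counts as matching itself); score = coverage * similarity. Columns
    where the reference row is gapped are skipped. Matching is
    case-insensitive.
    """
    rows = [str(r).upper() for r in alignment]
    if len(rows) < 2:
        raise InputError("alignment needs >= 2 rows")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise InputError("alignment rows have unequal lengths")
    mat = np.array([list(r) for r in rows])
    gaps = np.isin(mat, list(gap_chars))
    ref = mat[reference_row]
    ref_gap = gaps[reference_row]
    n = len(rows)
    covered = (~gaps).sum(axis=0)
    match = ((mat == ref[None, :]) & ~gaps).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coverage = covered / n
        similarity = np.where(covered > 0, match / np.maximum(covered, 1), 0.0)
    score = coverage * similarity
    keep = ~ref_gap
    cols = np.arange(L)[keep]
    return pd.DataFrame({"column": cols, "coverage": coverage[keep],
                         "similarity": similarity[keep],
                         "score": score[keep]}).reset_index(drop=True)
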