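"""Synthetic multi-species datasets with planted ground truth.

The generator emulates the statistical structure of a cross-species
brain/nonbrain study: negative-binomial bulk counts over several organs
per species, a one-to-one ortholog table, toy genome annotations with
epigenetic peaks of known cross-species class, block coordinate maps with
unmappable gaps, promoter-anchored loops wiring planted enhancers to
genes, fetal-zone FPKM tables, and clustered single-cell profiles.

Planted primate-specific brain-biased genes have their brain-tissue mean
multiplied by ``fold_effect`` in the primate species and divided by it in
the nonprimate and outgroup species, which is exactly the expression
signature the selection tree is designed to detect. One master seed
drives everything; each generator derives an independent stream from a
fixed label, so adding a generator never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import (BlockCoordinateMap, ExpressionStudy, GeneAnnotation,
                 IntervalSet, LoopSet, OrthologMap, write_bed,
                 write_block_map, write_counts, write_gene_annotation,
                 write_loops, write_orthologs)

# Fixed stream labels (never renumber: they pin determinism).
_STREAMS = {"expression": 1, "genomes": 2, "fetal": 3, "singlecell": 4}

ROLES = ("primateA", "primateB", "nonprimate", "outgroup")

DEFAULT_SPECIES = (("human", "primateA"), ("macaque", "primateB"),
                   ("treeshrew", "nonprimate"), ("mouse", "outgroup"))
DEFAULT_TISSUES = (("brain", "brain"), ("liver", "nonbrain"),
                   ("kidney", "nonbrain"), ("heart", "nonbrain"))
CELL_TYPES = ("NPC", "ExN", "IntN", "Astro", "Oligo", "OPC", "Micro",
              "Endo", "Peri", "MSN")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's defaults.

    ``species``: (name, role) pairs; roles primateA (reference primate),
    primateB (comparator primate), nonprimate, and an optional mouse-like
    outgroup. ``tissues``: (name, brain/nonbrain) pairs. ``fold_effect``
    is the planted expression multiplier; ``dispersion`` the
    negative-binomial overdispersion (var = mu + dispersion * mu^2).
    """

    n_genes: int = 2000
    species: tuple = DEFAULT_SPECIES
    tissues: tuple = DEFAULT_TISSUES
    samples_per_tissue: int = 10
    n_true_psbeg: int = 20
    fold_effect: float = 8.0
    dispersion: float = 0.1
    peak_width_bp: int = 500
    unmappable_fraction: float = 0.10
    seed: int = 0
    # toy-assembly / element layout
    gene_spacing: int = 10_000
    n_peaks: int = 300
    n_recnes: int = 50
    n_loops: int = 20
    epigenome_samples: int = 3
    # covariate structure
    confounded_covariates: bool = False
    # fetal-zone module
    fetal_zones: tuple = ("SVZ", "VZ", "aRG", "bRG")
    fetal_reps: int = 3
    n_fetal_pass: int = 3
    # single-cell module
    sc_clusters: int = 5
    sc_cells_per_cluster: int = 40
    sc_genes: int = 200
    n_sc_degs: int = 20
    sc_dispersion: float = 0.5
    # how many planted DEGs are wired (via loops) to enhancers of each class
    n_linked_human: int = 4
    n_linked_primate: int = 9

    def __post_init__(self):
        self.species = tuple((str(n), str(r)) for n, r in self.species)
        self.tissues = tuple((str(n), str(g)) for n, g in self.tissues)
        roles = [r for _, r in self.species]
        if len(self.species) < 3:
            raise ConfigurationError("need at least 3 species")
        for need in ("primateA", "primateB", "nonprimate"):
            if roles.count(need) != 1:
                raise ConfigurationError(
                    f"exactly one species must have role {need!r}")
        if roles.count("outgroup") > 1:
            raise ConfigurationError("at most one outgroup species")
        groups = {g for _, g in self.tissues}
        if not {"brain", "nonbrain"} <= groups:
            raise ConfigurationError(
                "need at least one brain and one nonbrain tissue")
        if not 0 < self.n_true_psbeg < self.n_genes:
            raise ConfigurationError(
                "n_true_psbeg must satisfy 0 < n_true_psbeg < n_genes")
        if self.fold_effect <= 0 or self.dispersion <= 0:
            raise ConfigurationError(
                "fold_effect and dispersion must be positive")
        if not 0 <= self.unmappable_fraction <= 1:
            raise ConfigurationError("unmappable_fraction must be in [0, 1]")
        if self.n_sc_degs > self.sc_genes or self.sc_genes > self.n_genes:
            raise ConfigurationError(
                "need n_sc_degs <= sc_genes <= n_genes")
        n_linked = self.n_linked_human + self.n_linked_primate
        if n_linked > self.n_sc_degs or n_linked > self.n_loops:
            raise ConfigurationError(
                "n_linked_human + n_linked_primate must not exceed "
                "n_sc_degs or n_loops")

    def role(self, role: str) -> str | None:
        for name, r in self.species:
            if r == role:
                return name
        return None

    @property
    def species_names(self) -> list[str]:
        return [n for n, _ in self.species]

    def gene_id(self, species: str, i: int) -> str:
        return f"{species}_g{i:05d}"


@dataclass
class GroundTruth:
    """Planted truth for every synthetic component (ids as generated)."""

    true_psbeg_ids: set = field(default_factory=set)
    true_peak_class: dict = field(default_factory=dict)
    element_to_gene: dict = field(default_factory=dict)
    fetal_pass_ids: set = field(default_factory=set)
    sc_deg: dict = field(default_factory=dict)      # cluster -> gene set
    cluster_labels: dict = field(default_factory=dict)
    linked_class_genes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, set):
                return sorted(x)
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            return x
        return json.dumps({k: conv(v) for k, v in
                           dataclasses.asdict(self).items()},
                          indent=1, sort_keys=True)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(config.seed)])


def _nb_draws(rng, mu, dispersion):
    """Negative binomial with mean mu and var mu + dispersion*mu^2."""
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# Bulk expression
# ---------------------------------------------------------------------------


def simulate_expression_study(config: SimulationConfig):
    """Per-species count tables with planted brain-biased genes.

    Returns (studies, ortholog_map, truth): ``studies`` maps species name
    to an :class:`ExpressionStudy`; gene ids are species-prefixed and tied
    together row-wise by the ortholog map.
    """
    rng = _rng(config, "expression")
    G = config.n_genes
    # shared biology: baseline means and per-tissue factors are the same
    # across species so orthologs agree apart from the planted effect
    base_mean = rng.lognormal(mean=np.log(150.0), sigma=0.8, size=G)
    tissue_factor = {
        t: rng.lognormal(mean=0.0, sigma=0.15, size=G)
        for t, _ in config.tissues}
    planted = np.sort(rng.choice(G, size=config.n_true_psbeg, replace=False))
    planted_mask = np.zeros(G, dtype=bool)
    planted_mask[planted] = True
    gene_lengths = rng.integers(500, 5000, size=G)

    ref = config.role("primateA")
    truth = GroundTruth(
        true_psbeg_ids={config.gene_id(ref, i) for i in planted})

    studies = {}
    for species, role in config.species:
        gene_ids = [config.gene_id(species, i) for i in range(G)]
        cols, meta_rows, blocks = [], [], []
        for tissue, group in config.tissues:
            for k in range(config.samples_per_tissue):
                sid = f"{species}_{tissue}_{k}"
                cols.append(sid)
                age = float(rng.uniform(2, 15))
                if config.confounded_covariates and group == "brain":
                    age += 10.0
                meta_rows.append({
                    "sample_id": sid, "species": species, "tissue": tissue,
                    "group": group, "age": round(age, 2),
                    "sex": "F" if k % 2 else "M",
                    "rin": round(float(np.clip(rng.normal(8, 0.5), 5, 10)), 2),
                    "uniquely_mapped_reads": int(rng.integers(15e6, 30e6)),
                    "unique_map_rate": round(float(rng.uniform(.75, .95)), 3),
                })
                mu = base_mean * tissue_factor[tissue]
                if group == "brain":
                    effect = np.ones(G)
                    if role in ("primateA", "primateB"):
                        effect[planted_mask] = config.fold_effect
                    else:
                        effect[planted_mask] = 1.0 / config.fold_effect
                    mu = mu * effect
                # mild per-sample depth variation exercises size factors
                depth = rng.lognormal(mean=0.0, sigma=0.2)
                blocks.append(_nb_draws(rng, mu * depth, config.dispersion))
        counts = pd.DataFrame(np.column_stack(blocks), index=gene_ids,
                              columns=cols)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        lengths = pd.Series(gene_lengths, index=gene_ids, name="length")
        studies[species] = ExpressionStudy(counts, meta, lengths)

    omap = OrthologMap(pd.DataFrame({
        sp: [config.gene_id(sp, i) for i in range(G)]
        for sp in config.species_names}))
    return studies, omap, truth


# ---------------------------------------------------------------------------
# Toy genomes, peaks, maps, loops
# ---------------------------------------------------------------------------


def _merge_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def _epigenome_roles(config: SimulationConfig):
    ref = config.role("primateA")
    comp = config.role("primateB")
    outg = config.role("outgroup") or config.role("nonprimate")
    return ref, comp, outg


def simulate_genomes_and_elements(config: SimulationConfig,
                                  truth: GroundTruth | None = None):
    """Toy assemblies, peaks with planted classes, maps, RECNEs, loops.

    All species share one toy chromosome in identity coordinates; the
    coordinate maps to the comparator and outgroup carry gaps so a
    configurable fraction of the reference assembly is unmappable, and
    peaks planted "absent" in a species are realized either as a mapped
    location with no peak or as an unmappable location. Loops wire planted
    enhancer peaks to planted genes' promoters. Returns a dict bundle and
    the (updated) GroundTruth.
    """
    if truth is None:
        truth = GroundTruth()
    rng = _rng(config, "genomes")
    ref, comp, outg = _epigenome_roles(config)
    others = [comp, outg]
    G, spacing = config.n_genes, config.gene_spacing
    W = config.peak_width_bp
    gene_region_end = G * spacing
    slot = 4 * W
    peak_region_start = gene_region_end + 10_000
    peak_region_end = peak_region_start + config.n_peaks * slot
    # a peak-free filler segment gives random unmappable gaps room to land
    filler = int(3 * config.unmappable_fraction * peak_region_end) + 10_000
    genome_len = peak_region_end + filler
    chrom = "chr1"

    annotations = {}
    for species in config.species_names:
        rows = [{"gene_id": config.gene_id(species, i), "chrom": chrom,
                 "start": i * spacing + 2000, "end": i * spacing + 6000,
                 "strand": "+" if i % 2 == 0 else "-"}
                for i in range(G)]
        annotations[species] = GeneAnnotation(pd.DataFrame(rows))

    # --- random peaks with planted class labels -------------------------
    classes = rng.choice(["human_all_shared", "primate_specific",
                          "human_specific"], size=config.n_peaks)
    slots = rng.permutation(config.n_peaks)
    peak_rows, mechanisms = [], {}
    for j in range(config.n_peaks):
        start = peak_region_start + slots[j] * slot + W
        name = f"pk{j:05d}"
        peak_rows.append({"chrom": chrom, "start": start, "end": start + W,
                          "name": name})
        truth.true_peak_class[name] = str(classes[j])
        absent_in = {"human_specific": others,
                     "primate_specific": [outg],
                     "human_all_shared": []}[classes[j]]
        for sp in absent_in:
            if config.unmappable_fraction > 0 and rng.random() < 0.5:
                mechanisms[(name, sp)] = "unmappable"
            else:
                mechanisms[(name, sp)] = "no_overlap"

    # --- planted enhancers linked to genes via loops ---------------------
    # the first planted loops target the planted single-cell DEG genes
    # (indices 0..n_sc_degs-1), so a known fraction of those DEGs carries a
    # human-specific or primate-specific regulatory element; the remaining
    # loops target other genes. Enhancers sit in promoter-free intergenic
    # zones counted down from the top of the gene region.
    loop_rows, enhancer_rows = [], []
    n_linked = config.n_linked_human + config.n_linked_primate
    n_loops = min(config.n_loops, G // 5)
    for k in range(n_loops):
        if k < n_linked:
            gi = k
            cls = ("human_specific" if k < config.n_linked_human
                   else "primate_specific")
        else:
            # stay clear of the planted DEG gene indices
            gi = max(config.n_sc_degs, n_linked) + (k - n_linked) * 5
            cls = "human_specific" if k % 2 == 0 else "primate_specific"
        target_zone = G - 1 - k
        if gi >= target_zone:
            break
        gene = annotations[ref].df.iloc[gi]
        e_start = target_zone * spacing + 8300
        e_name = f"enh{k:03d}"
        enhancer_rows.append({"chrom": chrom, "start": e_start,
                              "end": e_start + W, "name": e_name})
        # loop anchor A = the gene's promoter region, B = around the enhancer
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            a_start, a_end = max(0, tss - 2000), tss + 1000
        else:
            a_start, a_end = max(0, tss - 999), tss + 2001
        loop_rows.append({"chromA": chrom, "startA": a_start, "endA": a_end,
                          "chromB": chrom, "startB": e_start - 200,
                          "endB": e_start + W + 200,
                          "loop_id": f"loop{k:03d}"})
        truth.element_to_gene[e_name] = gene["gene_id"]
        # enhancer peaks carry a class so regulatory fractions are plantable
        truth.true_peak_class[e_name] = cls
        for sp in (others if cls == "human_specific" else [outg]):
            mechanisms[(e_name, sp)] = "no_overlap"
        truth.linked_class_genes.setdefault(cls, set()).add(gene["gene_id"])

    reference_peaks = IntervalSet(pd.DataFrame(peak_rows + enhancer_rows))

    # --- RECNEs placed just outside their gene (nearest by construction) --
    recne_rows = []
    recne_genes = rng.choice(G, size=min(config.n_recnes, G), replace=False)
    for k, gi in enumerate(np.sort(recne_genes)):
        start = gi * spacing + 6000 + int(rng.integers(200, 1200))
        name = f"recne{k:03d}"
        recne_rows.append({"chrom": chrom, "start": start,
                           "end": start + 200, "name": name})
        truth.element_to_gene[name] = config.gene_id(ref, int(gi))
    recnes = IntervalSet(pd.DataFrame(recne_rows))

    # --- coordinate maps: identity with gaps ------------------------------
    peak_by_name = {r["name"]: r for r in peak_rows + enhancer_rows}
    maps = {}
    for sp in others:
        gaps = [[peak_by_name[n]["start"] - 10, peak_by_name[n]["end"] + 10]
                for (n, s), mech in mechanisms.items()
                if s == sp and mech == "unmappable"]
        target_gap = config.unmappable_fraction * genome_len
        gap_total = sum(e - s for s, e in gaps)
        mappable_peaks = _merge_intervals(
            [(r["start"] - slot, r["end"] + slot)
             for r in peak_rows + enhancer_rows])
        attempts = 0
        while gap_total < target_gap and attempts < 50_000:
            attempts += 1
            s = int(rng.integers(0, genome_len - 2000))
            e = s + 2000
            # keep gene bodies, promoters, RECNEs and enhancers mappable,
            # and stay clear of every planted peak's slot
            if s < gene_region_end + 9000:
                continue
            if any(s < pe and e > ps for ps, pe in mappable_peaks):
                continue
            gaps.append([s, e])
            gap_total += 2000
        merged = _merge_intervals(gaps)
        blocks, pos = [], 0
        for gs, ge in merged:
            if gs > pos:
                blocks.append((pos, gs))
            pos = max(pos, ge)
        if pos < genome_len:
            blocks.append((pos, genome_len))
        maps[sp] = BlockCoordinateMap(pd.DataFrame(
            [{"src_chrom": chrom, "src_start": s, "src_end": e,
              "tgt_chrom": chrom, "tgt_start": s, "tgt_end": e,
              "orientation": "+"} for s, e in blocks]))

    # --- per-sample peak sets ---------------------------------------------
    species_samples = {}
    all_planted = peak_rows + enhancer_rows
    for sp in [ref] + others:
        samples = {}
        for si in range(config.epigenome_samples):
            rows = []
            for r in all_planted:
                name = r["name"]
                cls = truth.true_peak_class[name]
                present = (sp == ref or
                           (sp == comp and cls in ("human_all_shared",
                                                   "primate_specific")) or
                           (sp == outg and cls == "human_all_shared"))
                if not present:
                    continue
                jitter = int(rng.integers(-W // 4, W // 4 + 1))
                rows.append({"chrom": r["chrom"],
                             "start": max(0, r["start"] + jitter),
                             "end": r["end"] + jitter,
                             "name": f"{name}_{sp}_s{si}"})
            samples[f"{sp}_fetal_{si}"] = IntervalSet(pd.DataFrame(rows))
        species_samples[sp] = samples

    bundle = {"annotations": annotations, "reference_peaks": reference_peaks,
              "species_samples": species_samples, "maps": maps,
              "recnes": recnes, "loops": LoopSet(pd.DataFrame(loop_rows)),
              "enhancers": IntervalSet(pd.DataFrame(enhancer_rows)),
              "chrom_sizes": {chrom: genome_len},
              "roles": {"reference": ref, "comparator": comp,
                        "outgroup": outg}}
    return bundle, truth


# ---------------------------------------------------------------------------
# Fetal-zone FPKM tables
# ---------------------------------------------------------------------------


def simulate_fetal_zone_matrix(config: SimulationConfig,
                               truth: GroundTruth | None = None):
    """FPKM tables over fetal neocortex zones for human-like and
    mouse-like species (both indexed on the reference-species gene ids).

    Planted genes (a subset of the planted brain-biased genes when
    available) are active (FPKM in 2-10, so log2(FPKM+1) > 1) in every
    human sample and silent (< 0.5) in every mouse sample; other genes
    stay below the activity threshold in human.
    """
    if truth is None:
        truth = GroundTruth()
    rng = _rng(config, "fetal")
    ref = config.role("primateA")
    gene_ids = [config.gene_id(ref, i) for i in range(config.n_genes)]
    cols = [f"{z}_{r}" for z in config.fetal_zones
            for r in range(config.fetal_reps)]
    psbeg_sorted = sorted(truth.true_psbeg_ids)
    if psbeg_sorted:
        pass_ids = psbeg_sorted[:config.n_fetal_pass]
    else:
        pass_ids = gene_ids[:config.n_fetal_pass]
    truth.fetal_pass_ids = set(pass_ids)
    n, m = len(gene_ids), len(cols)
    human = rng.uniform(0.0, 0.9, size=(n, m))
    mouse = rng.uniform(0.0, 3.0, size=(n, m))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in pass_ids:
        human[idx[g]] = rng.uniform(2.0, 10.0, size=m)
        mouse[idx[g]] = rng.uniform(0.0, 0.5, size=m)
    fpkm_human = pd.DataFrame(human, index=gene_ids,
                              columns=[f"human_{c}" for c in cols])
    fpkm_mouse = pd.DataFrame(mouse, index=gene_ids,
                              columns=[f"mouse_{c}" for c in cols])
    return fpkm_human, fpkm_mouse, truth


# ---------------------------------------------------------------------------
# Single-cell clusters
# ---------------------------------------------------------------------------


def simulate_singlecell_clusters(config: SimulationConfig,
                                 truth: GroundTruth | None = None):
    """Clustered single-cell counts for two primates and a nonprimate.

    Planted cross-species DEGs are distributed round-robin over clusters:
    in their cluster the primate cells' mean is ``fold_effect`` times the
    nonprimate cells'. Comparator-primate cells carry reference cell-type
    labels, 80% the cluster's true type and 20% a neighboring type, to
    exercise majority-vote label transfer. Gene ids are on the reference
    universe (integrated data live on ortholog-anchored ids).
    """
    from .singlecell import CellTable

    if truth is None:
        truth = GroundTruth()
    rng = _rng(config, "singlecell")
    ref = config.role("primateA")
    comp = config.role("primateB")
    nonp = config.role("nonprimate")
    genes = [config.gene_id(ref, i) for i in range(config.sc_genes)]
    base = rng.lognormal(mean=np.log(2.0), sigma=1.0, size=config.sc_genes)
    deg_cluster = {}
    for j in range(config.n_sc_degs):
        deg_cluster[j] = j % config.sc_clusters
        truth.sc_deg.setdefault(j % config.sc_clusters, set()).add(genes[j])
    for c in range(config.sc_clusters):
        truth.sc_deg.setdefault(c, set())
        truth.cluster_labels[c] = CELL_TYPES[c % len(CELL_TYPES)]

    blocks, meta_rows = [], []
    for c in range(config.sc_clusters):
        # per-cluster expression signature shared by all species
        cluster_factor = rng.lognormal(mean=0.0, sigma=0.3,
                                       size=config.sc_genes)
        for species in (ref, comp, nonp):
            mu = base * cluster_factor
            effect = np.ones(config.sc_genes)
            for j, cl in deg_cluster.items():
                if cl == c:
                    effect[j] = (config.fold_effect
                                 if species in (ref, comp) else 1.0)
            mu = mu * effect
            for i in range(config.sc_cells_per_cluster):
                cid = f"{species}_c{c}_{i}"
                blocks.append(_nb_draws(rng, mu, config.sc_dispersion))
                row = {"cell_id": cid, "species": species, "cluster_id": c,
                       "reference_label": pd.NA}
                if species == comp:
                    true_type = truth.cluster_labels[c]
                    other = CELL_TYPES[(c + 1) % len(CELL_TYPES)]
                    row["reference_label"] = (true_type if
                                              i < 0.8 * config.
                                              sc_cells_per_cluster
                                              else other)
                meta_rows.append(row)
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    expr = pd.DataFrame(np.column_stack(blocks), index=genes,
                        columns=meta.index)
    return CellTable(expr, meta), truth


# ---------------------------------------------------------------------------
# Full dataset + serialization
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig):
    """Run every generator off one master seed; returns (dataset, truth)."""
    studies, omap, truth = simulate_expression_study(config)
    genome, truth = simulate_genomes_and_elements(config, truth)
    fpkm_human, fpkm_mouse, truth = simulate_fetal_zone_matrix(config, truth)
    cells, truth = simulate_singlecell_clusters(config, truth)
    dataset = {"studies": studies, "orthologs": omap, "genome": genome,
               "fpkm_human": fpkm_human, "fpkm_mouse": fpkm_mouse,
               "cells": cells}
    return dataset, truth


def write_simulation(dataset: dict, truth: GroundTruth, outdir) -> list:
    """Serialize a simulated dataset to plain-text files; returns the
    relative paths written (deterministic order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def path(name):
        written.append(name)
        return outdir / name

    for sp in sorted(dataset["studies"]):
        st = dataset["studies"][sp]
        write_counts(st, path(f"counts_{sp}.tsv"), path(f"meta_{sp}.tsv"),
                     path(f"gene_lengths_{sp}.tsv"))
    write_orthologs(dataset["orthologs"], path("orthologs.tsv"))
    genome = dataset["genome"]
    for sp in sorted(genome["annotations"]):
        write_gene_annotation(genome["annotations"][sp],
                              path(f"genes_{sp}.tsv"))
    write_bed(genome["reference_peaks"], path("reference_peaks.bed"))
    for sp in sorted(genome["species_samples"]):
        for sample in sorted(genome["species_samples"][sp]):
            write_bed(genome["species_samples"][sp][sample],
                      path(f"peaks_{sample}.bed"))
    for sp in sorted(genome["maps"]):
        write_block_map(genome["maps"][sp], path(f"map_to_{sp}.tsv"))
    write_bed(genome["recnes"], path("recnes.bed"))
    write_bed(genome["enhancers"], path("enhancers.bed"))
    write_loops(genome["loops"], path("loops.bedpe"))
    dataset["fpkm_human"].to_csv(path("fetal_fpkm_human.tsv"), sep="\t",
                                 index_label="gene_id")
    dataset["fpkm_mouse"].to_csv(path("fetal_fpkm_mouse.tsv"), sep="\t",
                                 index_label="gene_id")
    cells = dataset["cells"]
    cells.expression.to_csv(path("sc_expression.tsv"), sep="\t",
                            index_label="gene_id")
    cells.cell_meta.to_csv(path("sc_meta.tsv"), sep="\t",
                           index_label="cell_id")
    with open(path("ground_truth.json"), "w") as fh:
        fh.write(truth.to_json())
    return written
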