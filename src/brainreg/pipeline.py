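"""Configuration and end-to-end orchestration.

``run_pipeline`` executes simulate -> QC/DE -> selection tree -> fetal
filter -> peak classification -> loop assignment -> overlap tests ->
single-cell DEGs on one master seed, writes every stage's output as
plain text, and emits a deterministic manifest (config echo plus sha256
checksums of all outputs) so identical config+seed re-runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .expression import (brain_vs_nonbrain_de, covariate_screen,
                         filter_low_expression,
                         median_of_ratios_size_factors, qc_filter_samples)
from .epigenome import (assign_loops_to_promoters,
                        classify_cross_species_peaks)
from .orthology import link_elements_to_genes, promoter_windows
from .overlap import GeneSetCollection, interval_overlap_counts, overlap_matrix
from .psbeg import fetal_zone_filter, organ_summary, run_psbeg_pipeline
from .simulate import GroundTruth, SimulationConfig, simulate_all, \
    write_simulation
from .singlecell import (per_cluster_species_deg, regulatory_fraction,
                         transfer_cluster_labels)


@dataclass
class Thresholds:
    """Every decision threshold of the pipeline, exposed and auditable."""

    q: float = 0.05                      # DE FDR level
    lfc_min: float = 1.5                 # |log2FC| gate (inclusive)
    min_expr_fraction: float = 0.20      # expressed in > this fraction
    qc_min_reads: float = 12e6           # uniquely mapped reads, strict >
    qc_min_rate: float = 0.70            # unique mapping rate, strict >
    link_window_bp: int = 500_000        # element-to-gene window
    link_mode: str = "nearest"
    flank_bp: int = 2_000_000            # focal-gene scan flank
    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 1000
    fetal_threshold: float = 1.0         # on log2(FPKM+1)
    fetal_fraction: float = 0.80         # strict > of samples
    presence_rule: str = "all_samples"
    min_mapped_fraction: float = 0.95
    organ_stat: str = "median"
    sc_alpha: float = 0.05
    sc_adjust: str = "bonferroni"

    def __post_init__(self):
        checks = [
            (0 < self.q < 1, "q must be in (0, 1)"),
            (self.lfc_min >= 0, "lfc_min must be >= 0"),
            (0 <= self.min_expr_fraction < 1,
             "min_expr_fraction must be in [0, 1)"),
            (self.qc_min_reads >= 0, "qc_min_reads must be >= 0"),
            (0 <= self.qc_min_rate <= 1, "qc_min_rate must be in [0, 1]"),
            (self.link_window_bp > 0, "link_window_bp must be positive"),
            (self.link_mode in ("nearest", "all_within"),
             "link_mode must be nearest|all_within"),
            (self.flank_bp >= 0, "flank_bp must be >= 0"),
            (self.promoter_upstream_bp >= 0, "promoter_upstream_bp >= 0"),
            (self.promoter_downstream_bp >= 0, "promoter_downstream_bp >= 0"),
            (self.fetal_threshold >= 0, "fetal_threshold must be >= 0"),
            (0 < self.fetal_fraction < 1, "fetal_fraction must be in (0, 1)"),
            (0 < self.min_mapped_fraction <= 1,
             "min_mapped_fraction must be in (0, 1]"),
            (self.organ_stat in ("median", "mean"),
             "organ_stat must be median|mean"),
            (0 < self.sc_alpha < 1, "sc_alpha must be in (0, 1)"),
            (self.sc_adjust in ("bonferroni", "bh"),
             "sc_adjust must be bonferroni|bh"),
        ]
        if self.presence_rule not in ("all_samples", "any_sample"):
            try:
                f = float(self.presence_rule)
            except (TypeError, ValueError):
                raise ConfigurationError(
                    "presence_rule must be all_samples|any_sample|fraction")
            if not 0 < f <= 1:
                raise ConfigurationError(
                    "fractional presence_rule must be in (0, 1]")
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)

    @property
    def presence(self):
        if self.presence_rule in ("all_samples", "any_sample"):
            return self.presence_rule
        return float(self.presence_rule)


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        seed = raw.pop("seed", 0)
        sim_raw = dict(raw.pop("simulate", {}) or {})
        thr_raw = dict(raw.pop("thresholds", {}) or {})
        if raw:
            raise ConfigurationError(
                f"unknown config key(s): {sorted(raw)}")
        sim_fields = {f.name for f in fields(SimulationConfig)}
        unknown = set(sim_raw) - sim_fields
        if unknown:
            raise ConfigurationError(
                f"unknown simulate key(s): {sorted(unknown)}")
        thr_fields = {f.name for f in fields(Thresholds)}
        unknown = set(thr_raw) - thr_fields
        if unknown:
            raise ConfigurationError(
                f"unknown thresholds key(s): {sorted(unknown)}")
        sim_raw.setdefault("seed", seed)
        if not isinstance(seed, int):
            raise ConfigurationError("seed must be an integer")
        return cls(seed=seed, simulate=SimulationConfig(**sim_raw),
                   thresholds=Thresholds(**thr_raw))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def echo(self) -> dict:
        return {"seed": self.seed, "simulate": asdict(self.simulate),
                "thresholds": asdict(self.thresholds)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_expression(studies: dict, thresholds: Thresholds):
    """QC, filtering, covariate screening and DE for each species.

    Returns (de_results, organ_summaries, screens, filtered_studies).
    Organ summaries are computed on the QC'd (but not low-expression
    filtered) study so every universe gene keeps an organ profile.
    """
    de_results, summaries, screens, filtered = {}, {}, {}, {}
    for sp, study in studies.items():
        study = qc_filter_samples(study, thresholds.qc_min_reads,
                                  thresholds.qc_min_rate)
        sf = median_of_ratios_size_factors(study.counts)
        summaries[sp] = organ_summary(study, sf, thresholds.organ_stat)
        screen = covariate_screen(study)
        screens[sp] = screen
        flagged = list(screen["name"][screen["flagged"]])
        sub = filter_low_expression(study, thresholds.min_expr_fraction)
        de_results[sp] = brain_vs_nonbrain_de(
            sub, sf.reindex(sub.counts.columns), flagged,
            q=thresholds.q, lfc_min=thresholds.lfc_min)
        filtered[sp] = sub
    return de_results, summaries, screens, filtered


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages on a simulated dataset; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    stages: dict[str, list] = {}
    current = "simulate"

    def emit(stage, name, writer):
        p = outdir / name
        writer(p)
        stages.setdefault(stage, []).append(name)

    try:
        dataset, truth = simulate_all(config.simulate)
        inputs = write_simulation(dataset, truth, outdir / "inputs")
        stages["simulate"] = [f"inputs/{n}" for n in inputs]

        current = "expression_de"
        de_results, summaries, screens, _ = analyze_expression(
            dataset["studies"], thr)
        for sp in sorted(de_results):
            emit(current, f"de_{sp}.tsv",
                 lambda p, sp=sp: de_results[sp].to_csv(
                     p, sep="\t", index_label="gene_id"))
            emit(current, f"covariate_screen_{sp}.tsv",
                 lambda p, sp=sp: screens[sp].to_csv(p, sep="\t",
                                                     index=False))

        current = "psbeg_selection"
        cfg = config.simulate
        roles = dataset["genome"]["roles"]
        ref = roles["reference"]
        report = run_psbeg_pipeline(
            de_results, summaries, dataset["orthologs"],
            reference=ref, comparator=cfg.role("primateB"),
            nonprimate=cfg.role("nonprimate"), outgroup=cfg.role("outgroup"))
        fetal_pass = fetal_zone_filter(
            dataset["fpkm_human"], dataset["fpkm_mouse"], report.final_set,
            thr.fetal_threshold, thr.fetal_fraction)
        psbeg_json = {
            "counts": report.counts,
            "candidate_set": sorted(report.candidate_set),
            "final_set": sorted(report.final_set),
            "experimental_subset": sorted(report.experimental_subset),
            "fetal_pass": sorted(fetal_pass)}
        emit(current, "psbeg_report.json",
             lambda p: p.write_text(json.dumps(psbeg_json, indent=1,
                                               sort_keys=True)))
        emit(current, "psbeg_audit.tsv",
             lambda p: report.audit.to_csv(p, sep="\t"))

        current = "epigenome"
        genome = dataset["genome"]
        classes = classify_cross_species_peaks(
            genome["reference_peaks"], genome["species_samples"],
            genome["maps"], reference=ref, comparator=roles["comparator"],
            outgroup=roles["outgroup"], rule=thr.presence,
            min_mapped_fraction=thr.min_mapped_fraction)
        emit(current, "peak_classes.tsv",
             lambda p: classes.to_csv(p, sep="\t"))
        promoters = promoter_windows(genome["annotations"][ref],
                                     thr.promoter_upstream_bp,
                                     thr.promoter_downstream_bp)
        assignments = assign_loops_to_promoters(
            genome["loops"], promoters, genome["enhancers"])
        emit(current, "loop_assignments.tsv",
             lambda p: assignments.to_csv(p, sep="\t", index=False))
        recne_links = link_elements_to_genes(
            genome["recnes"], genome["annotations"][ref],
            thr.link_window_bp, thr.link_mode)
        emit(current, "recne_links.tsv",
             lambda p: recne_links.to_csv(p, sep="\t", index=False))

        current = "singlecell"
        cells = dataset["cells"]
        labels = transfer_cluster_labels(cells, roles["comparator"])
        emit(current, "cluster_labels.tsv",
             lambda p: labels.to_csv(p, sep="\t"))
        degs = per_cluster_species_deg(
            cells, ref, cfg.role("nonprimate"), alpha=thr.sc_alpha,
            adjust=thr.sc_adjust)
        emit(current, "sc_degs.tsv",
             lambda p: degs.to_csv(p, sep="\t", index=False))
        deg_set = set(degs["gene_id"])
        linked_by_class = {}
        class_of = classes["class"].to_dict()
        for _, row in assignments.iterrows():
            cls = class_of.get(row["element_id"])
            if isinstance(cls, str):
                linked_by_class.setdefault(cls, set()).add(row["gene_id"])
        for cls in ("human_specific", "primate_specific"):
            linked_by_class.setdefault(cls, set())
        fractions = regulatory_fraction(deg_set, linked_by_class)
        emit(current, "regulatory_fractions.tsv",
             lambda p: fractions.to_csv(p, sep="\t"))

        current = "overlap_stats"
        universe = dataset["orthologs"].universe(ref)
        collection = GeneSetCollection(universe, {
            "psbeg_final": report.final_set,
            "recne_linked": set(recne_links["gene_id"]) & universe,
            "sc_degs": deg_set & universe})
        omat = overlap_matrix(collection, ["recne_linked", "sc_degs"],
                              ["psbeg_final"], q=thr.q)
        emit(current, "overlap_tests.tsv",
             lambda p: omat.to_csv(p, sep="\t", index=False))
        from .io import IntervalSet
        human_specific = classes[classes["class"] == "human_specific"]
        hs_set = IntervalSet(human_specific.reset_index()[
            ["chrom", "start", "end", "name"]])
        region_counts = interval_overlap_counts(genome["recnes"], hs_set)
        emit(current, "recne_peak_overlap.json",
             lambda p: p.write_text(json.dumps(region_counts,
                                               sort_keys=True)))
    except Exception as exc:
        raise type(exc)(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "brainreg_version": __version__,
        "config": config.echo(),
        "stages": {
            stage: [{"path": name, "sha256": _sha256(outdir / name)}
                    for name in names]
            for stage, names in stages.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
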