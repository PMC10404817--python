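"""Coordinate mapping, peak presence/classification, loops, conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from brainreg.epigenome import (assign_loops_to_promoters,
                                classify_cross_species_peaks,
                                conservation_profile,
                                focal_gene_regulatory_scan, map_interval,
                                presence_verdict)
from brainreg.exceptions import ConfigurationError, InputError
from brainreg.io import (BlockCoordinateMap, GeneAnnotation, IntervalSet,
                         LoopSet)
from brainreg.orthology import promoter_windows


def _bmap(rows):
    return BlockCoordinateMap(pd.DataFrame(rows, columns=[
        "src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start",
        "tgt_end", "orientation"]))


IDENTITY = BlockCoordinateMap.identity({"chr1": 1_000_000})


class TestMapInterval:
    def test_identity_map_fixes_intervals(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = int(rng.integers(0, 999_000))
            e = s + int(rng.integers(1, 1000))
            assert map_interval(("chr1", s, e), IDENTITY) == ("chr1", s, e)

    def test_offset_within_plus_block_preserves_width(self):
        bmap = _bmap([("chr1", 100, 1000, "chr2", 150, 1050, "+")])
        assert map_interval(("chr1", 200, 300), bmap) == ("chr2", 250, 350)

    def test_half_in_gap_unmappable_at_default_threshold(self):
        bmap = _bmap([("chr1", 0, 100, "chr1", 0, 100, "+")])
        # interval [50, 150): 50% of bases beyond the block
        assert map_interval(("chr1", 50, 150), bmap) is None
        assert map_interval(("chr1", 50, 150), bmap,
                            min_mapped_fraction=0.5) == ("chr1", 50, 100)

    def test_split_target_chromosomes_fail(self):
        bmap = _bmap([("chr1", 0, 50, "chr2", 0, 50, "+"),
                      ("chr1", 50, 100, "chr3", 0, 50, "+")])
        assert map_interval(("chr1", 40, 60), bmap) is None

    def test_mixed_orientation_fails(self):
        bmap = _bmap([("chr1", 0, 50, "chr2", 0, 50, "+"),
                      ("chr1", 50, 100, "chr2", 100, 150, "-")])
        assert map_interval(("chr1", 40, 60), bmap) is None

    def test_round_trip_through_inverse(self):
        bmap = _bmap([("chr1", 0, 500, "chr2", 1000, 1500, "+"),
                      ("chr1", 700, 900, "chr2", 2000, 2200, "-")])
        inv = bmap.inverse()
        for (s, e) in [(10, 100), (250, 400), (710, 890), (700, 900)]:
            mapped = map_interval(("chr1", s, e), bmap)
            assert mapped is not None
            back = map_interval(mapped, inv)
            assert back == ("chr1", s, e)


class TestPresence:
    peak = IntervalSet.from_records([("chr1", 100, 200, "p")])
    empty = IntervalSet(pd.DataFrame({"chrom": [], "start": [], "end": [],
                                      "name": []}))

    def _samples(self, n_with, n_without):
        d = {}
        for i in range(n_with):
            d[f"w{i}"] = self.peak
        for i in range(n_without):
            d[f"o{i}"] = self.empty
        return d

    def test_all_samples_rule(self):
        iv = ("chr1", 150, 160)
        assert presence_verdict(iv, self._samples(16, 0)) == "present"
        assert presence_verdict(iv, self._samples(15, 1)) == "absent"

    def test_fraction_rule(self):
        iv = ("chr1", 150, 160)
        assert presence_verdict(iv, self._samples(15, 1), rule=0.9) == \
            "present"
        assert presence_verdict(iv, self._samples(14, 2), rule=0.9) == \
            "absent"

    def test_any_sample_rule(self):
        iv = ("chr1", 150, 160)
        assert presence_verdict(iv, self._samples(1, 15),
                                rule="any_sample") == "present"

    def test_zero_samples_is_error(self):
        with pytest.raises(InputError):
            presence_verdict(("chr1", 0, 1), {})


def _truth_table_fixture():
    """One reference peak per evidence combination for two species."""
    W = 100
    states = ["present", "absent", "unmappable"]
    combos = list(itertools.product(states, states))
    peaks, gap_rows = [], {"comp": [], "outg": []}
    sample_peaks = {"human": [], "comp": [], "outg": []}
    for i, (comp_state, outg_state) in enumerate(combos):
        s = 10_000 * i + 1000
        name = f"tt{i}"
        peaks.append(("chr1", s, s + W, name))
        sample_peaks["human"].append(("chr1", s, s + W, name + "_h"))
        for sp, state in (("comp", comp_state), ("outg", outg_state)):
            if state == "present":
                sample_peaks[sp].append(("chr1", s, s + W, name + "_" + sp))
            elif state == "unmappable":
                gap_rows[sp].append((s - 10, s + W + 10))
    L = 10_000 * len(combos) + 10_000
    maps = {}
    for sp in ("comp", "outg"):
        blocks, pos = [], 0
        for gs, ge in gap_rows[sp]:
            blocks.append(("chr1", pos, gs, "chr1", pos, gs, "+"))
            pos = ge
        blocks.append(("chr1", pos, L, "chr1", pos, L, "+"))
        maps[sp] = _bmap(blocks)
    species_samples = {
        sp: {f"{sp}_s0": IntervalSet.from_records(recs),
             f"{sp}_s1": IntervalSet.from_records(
                 [(c, s, e, n + "b") for c, s, e, n in recs])}
        for sp, recs in sample_peaks.items()}
    ref_peaks = IntervalSet.from_records(peaks)
    return ref_peaks, species_samples, maps, combos


def expected_class(comp_state, outg_state):
    comp_absent = comp_state != "present"
    outg_absent = outg_state != "present"
    if comp_absent and outg_absent:
        return "human_specific"
    if not comp_absent and outg_absent:
        return "primate_specific"
    return "human_all_shared"


class TestClassification:
    def test_nine_combination_truth_table(self):
        ref_peaks, samples, maps, combos = _truth_table_fixture()
        out = classify_cross_species_peaks(
            ref_peaks, samples, maps, reference="human",
            comparator="comp", outgroup="outg")
        for i, (comp_state, outg_state) in enumerate(combos):
            row = out.loc[f"tt{i}"]
            assert row["class"] == expected_class(comp_state, outg_state)
            assert row["evidence_comp"] == comp_state
            assert row["evidence_outg"] == outg_state

    def test_classes_partition_reference_present_peaks(self):
        ref_peaks, samples, maps, _ = _truth_table_fixture()
        out = classify_cross_species_peaks(
            ref_peaks, samples, maps, reference="human",
            comparator="comp", outgroup="outg")
        assert out["class"].notna().all()
        assert out["class"].isin(["human_specific", "primate_specific",
                                  "human_all_shared"]).all()

    def test_missing_map_is_configuration_error(self):
        ref_peaks, samples, maps, _ = _truth_table_fixture()
        with pytest.raises(ConfigurationError):
            classify_cross_species_peaks(
                ref_peaks, samples, {"comp": maps["comp"]},
                reference="human", comparator="comp", outgroup="outg")

    def test_synthetic_genome_confusion_diagonal(self, small_dataset):
        dataset, truth = small_dataset
        g = dataset["genome"]
        out = classify_cross_species_peaks(
            g["reference_peaks"], g["species_samples"], g["maps"],
            reference=g["roles"]["reference"],
            comparator=g["roles"]["comparator"],
            outgroup=g["roles"]["outgroup"])
        for name, cls in truth.true_peak_class.items():
            assert out.loc[name, "class"] == cls


class TestFocalScan:
    def _setup(self):
        gene = {"gene_id": "focal", "chrom": "chr1",
                "start": 5_000_000, "end": 5_100_000, "strand": "+"}
        peaks = IntervalSet.from_records([
            ("chr1", 5_000_000 - 1_900_000, 5_000_000 - 1_899_500, "near"),
            ("chr1", 5_000_000 - 2_100_000, 5_000_000 - 2_099_500, "far"),
            ("chr1", 5_050_000, 5_050_500, "inside_shared")])
        bmap = BlockCoordinateMap.identity({"chr1": 10_000_000})
        outg = {"s0": IntervalSet.from_records(
            [("chr1", 5_050_000, 5_050_500, "shared_outg")])}
        return gene, peaks, bmap, outg

    def test_window_arithmetic_and_shared_exclusion(self):
        gene, peaks, bmap, outg = self._setup()
        hits = focal_gene_regulatory_scan(gene, peaks, outg, bmap)
        names = set(hits.df["name"])
        assert "near" in names          # 1.9 Mb upstream: in window
        assert "far" not in names       # 2.1 Mb upstream: out of window
        assert "inside_shared" not in names   # maps onto an outgroup peak

    def test_planted_specific_peaks_recovered(self, small_dataset):
        dataset, truth = small_dataset
        g = dataset["genome"]
        ref = g["roles"]["reference"]
        outg = g["roles"]["outgroup"]
        # scan a gene physically adjacent to a planted human-specific
        # enhancer (loop targets are long-range; the scan is positional)
        enh_row = g["enhancers"].df.iloc[0]
        assert truth.true_peak_class[enh_row["name"]] == "human_specific"
        ann = g["annotations"][ref].df
        near = ann[(ann["start"] - 2_000_000 < enh_row["start"]) &
                   (ann["end"] + 2_000_000 > enh_row["end"])].iloc[-1]
        hits = focal_gene_regulatory_scan(
            near, g["reference_peaks"], g["species_samples"][outg],
            g["maps"][outg])
        names = set(hits.df["name"])
        assert enh_row["name"] in names
        # every returned peak is genuinely non-shared per ground truth
        assert all(truth.true_peak_class[n] != "human_all_shared"
                   for n in names)


class TestLoopAssignment:
    def test_simple_loop_distal(self):
        genes = GeneAnnotation(pd.DataFrame([
            {"gene_id": "G", "chrom": "chr1", "start": 100_000,
             "end": 110_000, "strand": "+"}]))
        proms = promoter_windows(genes)
        loops = LoopSet(pd.DataFrame([{
            "chromA": "chr1", "startA": 98_500, "endA": 100_500,
            "chromB": "chr1", "startB": 500_000, "endB": 502_000,
            "loop_id": "L"}]))
        elements = IntervalSet.from_records(
            [("chr1", 500_500, 501_000, "E"),
             ("chr1", 900_000, 900_500, "lonely")])
        out = assign_loops_to_promoters(loops, proms, elements)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["gene_id"], row["element_id"], row["route"]) == \
            ("G", "E", "loop_distal")

    def test_both_anchors_in_promoters_dual_route(self):
        genes = GeneAnnotation(pd.DataFrame([
            {"gene_id": "G1", "chrom": "chr1", "start": 100_000,
             "end": 110_000, "strand": "+"},
            {"gene_id": "G2", "chrom": "chr1", "start": 500_000,
             "end": 510_000, "strand": "+"}]))
        proms = promoter_windows(genes)
        loops = LoopSet(pd.DataFrame([{
            "chromA": "chr1", "startA": 98_500, "endA": 100_500,
            "chromB": "chr1", "startB": 498_500, "endB": 500_500,
            "loop_id": "L"}]))
        elements = IntervalSet.from_records([("chr1", 499_000, 499_400,
                                              "E")])
        out = assign_loops_to_promoters(loops, proms, elements)
        routes = {(r["gene_id"], r["route"]) for _, r in out.iterrows()}
        assert ("G1", "loop_distal") in routes     # via the loop
        assert ("G2", "promoter_overlap") in routes  # direct overlap

    def test_planted_loops_recover_element_to_gene(self, small_dataset):
        dataset, truth = small_dataset
        g = dataset["genome"]
        ref = g["roles"]["reference"]
        proms = promoter_windows(g["annotations"][ref])
        out = assign_loops_to_promoters(g["loops"], proms, g["enhancers"])
        distal = out[out["route"] == "loop_distal"]
        got = dict(zip(distal["element_id"], distal["gene_id"]))
        expected = {e: gid for e, gid in truth.element_to_gene.items()
                    if e.startswith("enh")}
        assert got == expected


class TestConservationProfile:
    def test_identical_rows_score_one(self):
        prof = conservation_profile(["ACGT"] * 4)
        np.testing.assert_allclose(prof["score"], 1.0)

    def test_one_gap_coverage(self):
        prof = conservation_profile(["ACGT", "AC-T", "ACGT", "ACGT"])
        col2 = prof[prof["column"] == 2].iloc[0]
        assert col2["coverage"] == pytest.approx(0.75)
        assert col2["similarity"] == pytest.approx(1.0)
        assert col2["score"] == pytest.approx(0.75)

    def test_half_matching_rows(self):
        # 4 covered rows, 2 match the reference residue (incl. reference)
        prof = conservation_profile(["AAAA", "AAAA", "CCCC", "CCCC"])
        np.testing.assert_allclose(prof["coverage"], 1.0)
        np.testing.assert_allclose(prof["similarity"], 0.5)
        np.testing.assert_allclose(prof["score"], 0.5)

    def test_reference_gap_columns_skipped(self):
        prof = conservation_profile(["A-GT", "ACGT", "ACGT"])
        assert list(prof["column"]) == [0, 2, 3]

    def test_row_order_invariance(self):
        rows = ["ACGTACGT", "AC-TACCT", "GCGTAC-T", "ACTTACGA"]
        prof1 = conservation_profile(rows)
        shuffled = [rows[0], rows[2], rows[3], rows[1]]
        prof2 = conservation_profile(shuffled)
        pd.testing.assert_frame_equal(prof1, prof2)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            conservation_profile(["ACGT", "ACG"])
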