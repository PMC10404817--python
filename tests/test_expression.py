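"""Normalization, QC boundaries, covariate screen, BH, and the DE engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainreg.exceptions import EstimationError, InputError
from brainreg.expression import (bh_adjust, brain_vs_nonbrain_de,
                                 compute_tpm_fpkm, covariate_screen,
                                 filter_low_expression,
                                 median_of_ratios_size_factors,
                                 qc_filter_samples)
from brainreg.io import ExpressionStudy
from brainreg.simulate import SimulationConfig, simulate_expression_study


def _study(counts, groups, **meta_cols):
    samples = list(counts.columns)
    meta = pd.DataFrame({
        "species": "h", "tissue": ["brain" if g == "brain" else "liver"
                                   for g in groups],
        "group": groups}, index=pd.Index(samples, name="sample_id"))
    for k, v in meta_cols.items():
        meta[k] = v
    return ExpressionStudy(counts, meta)


class TestQcAndFiltering:
    def _qc_study(self, reads, rate):
        counts = pd.DataFrame({"s1": [5], "s2": [5]}, index=["g1"])
        return _study(counts, ["brain", "nonbrain"],
                      uniquely_mapped_reads=[reads, 20e6],
                      unique_map_rate=[rate, 0.9])

    @pytest.mark.parametrize("reads,rate,kept", [
        (12_000_000, 0.9, False),   # exactly 12M: strict >
        (15_000_000, 0.69, False),
        (15_000_000, 0.71, True),
        (15_000_000, 0.70, False),  # exactly 0.70: strict >
        (12_000_001, 0.71, True),
    ])
    def test_qc_boundaries(self, reads, rate, kept):
        out = qc_filter_samples(self._qc_study(reads, rate))
        assert ("s1" in out.samples) == kept

    def test_missing_qc_fields(self):
        counts = pd.DataFrame({"s1": [5], "s2": [5]}, index=["g1"])
        with pytest.raises(InputError):
            qc_filter_samples(_study(counts, ["brain", "nonbrain"]))

    @pytest.mark.parametrize("n_nonzero,kept", [(0, False), (2, False),
                                                (3, True)])
    def test_low_expression_strict_20pct(self, n_nonzero, kept):
        row = [1] * n_nonzero + [0] * (10 - n_nonzero)
        counts = pd.DataFrame([row, [5] * 10],
                              index=["g", "ref"],
                              columns=[f"s{i}" for i in range(10)])
        st = _study(counts, ["brain"] * 5 + ["nonbrain"] * 5)
        out = filter_low_expression(st)
        assert ("g" in out.genes) == kept


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [3, 7], "s2": [3, 7]}, index=["a", "b"])
        np.testing.assert_allclose(
            median_of_ratios_size_factors(counts), [1.0, 1.0])

    def test_hand_computed_example(self):
        counts = pd.DataFrame({"s1": [2, 2], "s2": [8, 8]}, index=["a", "b"])
        np.testing.assert_allclose(
            median_of_ratios_size_factors(counts), [0.5, 2.0])

    def test_scale_equivariance_and_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (50, 4)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        sf = median_of_ratios_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 10
        sf2 = median_of_ratios_size_factors(scaled)
        # scaling one sample by c rescales the geometric-mean reference,
        # so equivariance holds for factor RATIOS between samples
        np.testing.assert_allclose(sf2["b"] / sf2["a"],
                                   10 * sf["b"] / sf["a"])
        np.testing.assert_allclose(sf2["c"] / sf2["a"], sf["c"] / sf["a"])
        shuffled = counts.sample(frac=1, random_state=1)
        np.testing.assert_allclose(
            median_of_ratios_size_factors(shuffled), sf)

    def test_no_eligible_gene_raises(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]}, index=["a", "b"])
        with pytest.raises(EstimationError):
            median_of_ratios_size_factors(counts)


class TestTpmFpkm:
    def test_single_gene_tpm_is_1e6(self):
        counts = pd.DataFrame({"s1": [17]}, index=["g"])
        tpm, _ = compute_tpm_fpkm(counts, pd.Series({"g": 1000}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_length_ratio_and_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["short", "long"])
        lengths = pd.Series({"short": 1000, "long": 2000})
        tpm, fpkm = compute_tpm_fpkm(counts, lengths)
        assert tpm.loc["short", "s1"] / tpm.loc["long", "s1"] == 2
        tpm2, _ = compute_tpm_fpkm(counts * 2, lengths)
        pd.testing.assert_frame_equal(tpm, tpm2)
        # FPKM formula spot check: 10 * 1e9 / (1000 * 20)
        assert fpkm.loc["short", "s1"] == 10 * 1e9 / (1000 * 20)

    def test_tpm_columns_sum_to_1e6(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, (30, 3)),
                              index=[f"g{i}" for i in range(30)],
                              columns=list("xyz"))
        lengths = pd.Series(rng.integers(200, 5000, 30), index=counts.index)
        tpm, _ = compute_tpm_fpkm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6)


class TestCovariateScreen:
    def test_identical_distributions_not_flagged(self):
        counts = pd.DataFrame(np.ones((2, 6), dtype=int),
                              index=["a", "b"],
                              columns=[f"s{i}" for i in range(6)])
        st = _study(counts, ["brain"] * 3 + ["nonbrain"] * 3,
                    age=[5, 6, 7, 5, 6, 7], sex=list("MFM") * 2,
                    rin=[8.0] * 6)
        rep = covariate_screen(st).set_index("name")
        assert not rep["flagged"].any()
        # constant covariate: p = 1 by convention
        assert rep.loc["rin", "p"] == 1.0

    def test_exact_u_p_of_separated_ages(self):
        # brain (1,2,3) vs nonbrain (10,11,12): exact two-sided p = 2/20
        counts = pd.DataFrame(np.ones((2, 6), dtype=int),
                              index=["a", "b"],
                              columns=[f"s{i}" for i in range(6)])
        st = _study(counts, ["brain"] * 3 + ["nonbrain"] * 3,
                    age=[1, 2, 3, 10, 11, 12])
        rep = covariate_screen(st).set_index("name")
        assert rep.loc["age", "p"] == pytest.approx(0.1)
        assert not rep.loc["age", "flagged"]

    def test_confounded_sex_flagged_via_fisher(self):
        counts = pd.DataFrame(np.ones((2, 10), dtype=int),
                              index=["a", "b"],
                              columns=[f"s{i}" for i in range(10)])
        st = _study(counts, ["brain"] * 5 + ["nonbrain"] * 5,
                    sex=["M"] * 5 + ["F"] * 5)
        rep = covariate_screen(st).set_index("name")
        # hypergeometric tail of the fully confounded 2x2 table
        expected = stats.fisher_exact([[0, 5], [5, 0]])[1]
        assert rep.loc["sex", "p"] == pytest.approx(expected)
        assert rep.loc["sex", "flagged"]


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])


class TestDeEngine:
    def _two_group(self, a, b):
        counts = pd.DataFrame(
            np.vstack([np.concatenate([a, b])]).astype(int),
            index=["g"], columns=[f"s{i}" for i in range(len(a) + len(b))])
        ref = pd.DataFrame([[50] * (len(a) + len(b))], index=["ref"],
                           columns=counts.columns)
        counts = pd.concat([counts, ref])
        return _study(counts, ["brain"] * len(a) + ["nonbrain"] * len(b))

    def test_lfc_gate_blocks_significant_small_effects(self):
        # a gene with tiny p but |log2fc| < 1.5 must stay ns
        rng = np.random.default_rng(4)
        n = 200
        base = rng.integers(95, 105, 2 * n)
        counts = pd.DataFrame({f"s{i}": [base[i], 50] for i in range(2 * n)},
                              index=["g", "ref"])
        counts.loc["g", counts.columns[:n]] += 40   # ~0.5 log2fc, huge n
        st = _study(counts, ["brain"] * n + ["nonbrain"] * n)
        res = brain_vs_nonbrain_de(st, pd.Series(1.0, counts.columns))
        assert res.loc["g", "p"] < 1e-9
        assert abs(res.loc["g", "log2fc"]) < 1.5
        assert res.loc["g", "call"] == "ns"

    def test_planted_gene_called_up_in_brain(self):
        cfg = SimulationConfig(n_genes=300, n_true_psbeg=5, seed=5)
        studies, omap, truth = simulate_expression_study(cfg)
        res = brain_vs_nonbrain_de(studies["human"])
        planted = sorted(truth.true_psbeg_ids)
        assert (res.loc[planted, "call"] == "up_in_brain").all()
        # and in the nonprimate the same orthologs are down in brain
        tres = brain_vs_nonbrain_de(studies["treeshrew"])
        t_ids = [p.replace("human_", "treeshrew_") for p in planted]
        assert (tres.loc[t_ids, "call"] == "down_in_brain").all()

    def test_matches_welch_t_without_covariates(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.integers(1, 300, (40, 12)),
                              index=[f"g{i}" for i in range(40)],
                              columns=[f"s{i}" for i in range(12)])
        st = _study(counts, ["brain"] * 6 + ["nonbrain"] * 6)
        sf = pd.Series(1.0, counts.columns)
        res = brain_vs_nonbrain_de(st, sf)
        y = np.log2(counts.to_numpy(float) + 1)
        ref = stats.ttest_ind(y[:, :6], y[:, 6:], axis=1, equal_var=False)
        np.testing.assert_allclose(res["p"], ref.pvalue)

    def test_collinear_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(1, 300, (10, 8)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(8)])
        st = _study(counts, ["brain"] * 4 + ["nonbrain"] * 4,
                    age=[1.0] * 4 + [2.0] * 4)   # perfectly confounded
        with pytest.warns(UserWarning, match="collinear"):
            res = brain_vs_nonbrain_de(st, pd.Series(1.0, counts.columns),
                                       covariates=["age"])
        assert len(res) == 10

    def test_covariate_adjustment_changes_inference_sensibly(self):
        # a balanced covariate explaining variance should not break calls
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(50, 150, (20, 12)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(12)])
        st = _study(counts, ["brain"] * 6 + ["nonbrain"] * 6,
                    age=[1, 2, 3, 4, 5, 6] * 2)
        res = brain_vs_nonbrain_de(st, pd.Series(1.0, counts.columns),
                                   covariates=["age"])
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
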