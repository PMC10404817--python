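"""QC, normalization, covariate screening and brain-vs-nonbrain DE.

The differential-expression engine is a deterministic linear model on
log2 median-of-ratios-normalized counts: with no flagged covariates it is
a Welch two-sample t-test per gene; flagged covariates enter an OLS design
alongside the group term. The decision rule matches standard RNA-seq
practice here: BH-adjusted FDR < q and |log2 fold change| >= lfc_min.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, InputError
from .io import ExpressionStudy

log = logging.getLogger(__name__)

NUMERIC_COVARIATES = ("age", "rin")
CATEGORICAL_COVARIATES = ("sex",)


def qc_filter_samples(study: ExpressionStudy, min_reads: float = 12e6,
                      min_rate: float = 0.70) -> ExpressionStudy:
    """Retain samples with uniquely mapped reads strictly greater than
    ``min_reads`` AND unique mapping rate strictly greater than ``min_rate``."""
    meta = study.sample_meta
    for col in ("uniquely_mapped_reads", "unique_map_rate"):
        if col not in meta.columns:
            raise InputError(f"sample metadata lacks QC field {col!r}")
    keep = (meta["uniquely_mapped_reads"] > min_reads) & \
           (meta["unique_map_rate"] > min_rate)
    removed = meta.index[~keep]
    if len(removed):
        log.info("QC removed %d sample(s): %s", len(removed),
                 ", ".join(removed[:10]))
    return study.subset_samples(list(meta.index[keep]))


def filter_low_expression(study: ExpressionStudy,
                          min_fraction: float = 0.20) -> ExpressionStudy:
    """Retain genes expressed (count > 0) in strictly more than
    ``min_fraction`` of samples."""
    frac = (study.counts > 0).mean(axis=1)
    keep = study.counts.index[frac > min_fraction]
    return study.subset_genes(keep)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    factor_j = median over eligible genes of count_gj / geomean_g, where
    eligible genes have positive counts in every sample (genes with a zero
    geometric mean are excluded; the exclusion count is logged).
    """
    arr = counts.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    n_excluded = int((~eligible).sum())
    if not eligible.any():
        raise EstimationError(
            "no gene with all-positive counts; size factors undefined")
    if n_excluded:
        log.info("size factors: %d gene(s) with zero counts excluded",
                 n_excluded)
    sub = arr[eligible]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def compute_tpm_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series):
    """TPM and FPKM tables from raw counts and gene lengths (bp).

    FPKM_gj = count_gj * 1e9 / (length_g * libsize_j);
    TPM_gj = rate_gj * 1e6 / sum_g rate_gj with rate = count / length.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise InputError("gene_lengths missing some genes")
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    arr = counts.to_numpy(dtype=float)
    libsize = arr.sum(axis=0)
    if (libsize == 0).any():
        raise EstimationError("zero library size in at least one sample")
    L = lengths.to_numpy()[:, None]
    fpkm = arr * 1e9 / (L * libsize[None, :])
    rate = arr / L
    tpm = rate * 1e6 / rate.sum(axis=0)[None, :]
    fpkm = pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)
    tpm = pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
    return tpm, fpkm


def covariate_screen(study: ExpressionStudy) -> pd.DataFrame:
    """Test each known covariate for imbalance between brain and nonbrain.

    Numeric covariates (age, RIN): two-sided Mann-Whitney U. Categorical
    (sex): Fisher exact on the 2x2 table. Flagged when p < 0.05; constant
    covariates get p = 1 and are never flagged.
    """
    meta = study.sample_meta
    is_brain = (meta["group"] == "brain").to_numpy()
    rows = []
    for name in NUMERIC_COVARIATES:
        if name not in meta.columns:
            continue
        x = meta[name].to_numpy(dtype=float)[is_brain]
        y = meta[name].to_numpy(dtype=float)[~is_brain]
        if np.unique(np.concatenate([x, y])).size <= 1:
            stat, p = np.nan, 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"name": name, "test": "mann-whitney-u",
                     "statistic": stat, "p": p, "flagged": p < 0.05})
    for name in CATEGORICAL_COVARIATES:
        if name not in meta.columns:
            continue
        vals = meta[name].astype(str)
        levels = sorted(vals.unique())
        if len(levels) <= 1:
            rows.append({"name": name, "test": "fisher-exact",
                         "statistic": np.nan, "p": 1.0, "flagged": False})
            continue
        table = np.array([
            [(vals[is_brain] == lv).sum() for lv in levels[:2]],
            [(vals[~is_brain] == lv).sum() for lv in levels[:2]]])
        odds, p = stats.fisher_exact(table)
        rows.append({"name": name, "test": "fisher-exact",
                     "statistic": float(odds), "p": float(p),
                     "flagged": p < 0.05})
    return pd.DataFrame(rows, columns=["name", "test", "statistic", "p",
                                       "flagged"])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order restored, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if (~np.isfinite(p)).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def _design_matrix(meta: pd.DataFrame, covariates: list[str],
                   group_vec: np.ndarray):
    """Build [intercept, group, covariates...]; drop covariates collinear
    with the existing columns (warning)."""
    n = len(meta)
    cols = [np.ones(n), group_vec.astype(float)]
    names = ["intercept", "group"]
    for name in covariates:
        if name in CATEGORICAL_COVARIATES:
            vals = meta[name].astype(str)
            levels = sorted(vals.unique())
            if len(levels) <= 1:
                continue
            vec = (vals == levels[1]).to_numpy(dtype=float)
        else:
            vec = meta[name].to_numpy(dtype=float)
        X_try = np.column_stack(cols + [vec])
        if np.linalg.matrix_rank(X_try) <= len(cols):
            warnings.warn(
                f"covariate {name!r} is collinear with the design; dropped",
                stacklevel=3)
            continue
        cols.append(vec)
        names.append(name)
    return np.column_stack(cols), names


def brain_vs_nonbrain_de(study: ExpressionStudy,
                         size_factors: pd.Series | None = None,
                         covariates: list[str] | None = None,
                         q: float = 0.05,
                         lfc_min: float = 1.5) -> pd.DataFrame:
    """Per-gene brain-vs-nonbrain differential expression.

    y = log2(count / size_factor + 1). With no covariates the group term is
    tested by Welch's t; with covariates an OLS fit of y ~ group + covariates
    tests the group coefficient. log2fc is always the difference of group
    means of y (brain minus nonbrain). Calls: ``up_in_brain`` /
    ``down_in_brain`` when fdr < q AND |log2fc| >= lfc_min, else ``ns``.
    """
    meta = study.sample_meta
    is_brain = (meta["group"] == "brain").to_numpy()
    if is_brain.sum() < 2 or (~is_brain).sum() < 2:
        raise InputError("need >= 2 samples per group for DE")
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(study.counts)
    sf = size_factors.reindex(study.counts.columns).to_numpy(dtype=float)
    y = np.log2(study.counts.to_numpy(dtype=float) / sf[None, :] + 1.0)

    lfc = y[:, is_brain].mean(axis=1) - y[:, ~is_brain].mean(axis=1)

    covariates = [c for c in (covariates or [])]
    if covariates:
        X, _names = _design_matrix(meta, covariates, is_brain)
        n, k = X.shape
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = y @ (XtX_inv @ X.T).T              # genes x k
        resid = y - beta @ X.T
        dof = n - k
        sigma2 = (resid ** 2).sum(axis=1) / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[:, 1] / se
        p = 2 * stats.t.sf(np.abs(t), dof)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(y[:, is_brain], y[:, ~is_brain], axis=1,
                                  equal_var=False)
        p = np.asarray(res.pvalue)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = bh_adjust(p)
    call = np.where((fdr < q) & (np.abs(lfc) >= lfc_min),
                    np.where(lfc > 0, "up_in_brain", "down_in_brain"), "ns")
    return pd.DataFrame({"log2fc": lfc, "p": p, "fdr": fdr, "call": call},
                        index=study.counts.index)
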