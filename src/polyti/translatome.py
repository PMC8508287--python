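"""Translational-index analysis of polysome-profiling count data.

Per expressed gene the translational index is

    TI = x1 / x2,   x1 = mean(poly, T) / mean(cyto, T),
                    x2 = mean(poly, NT) / mean(cyto, NT)

on size-factor-normalized counts; log2 TI > 0 means the mRNA is more
efficiently recruited to polysomes under treatment.  Significance comes
from a two-sided permutation test of the fraction x condition
interaction: condition labels are permuted among the samples of each
gradient fraction and the log2 TI recomputed for every relabelling
(exhaustively when the number of distinct relabellings is small enough,
Monte-Carlo otherwise).  Benjamini-Hochberg adjustment controls the FDR
across genes, and genes are called translationally up / down / stable by
a fold cut-off on |log2 TI| combined with the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from polyti.io import CountDataset

_TOL = 1e-12  # absolute slack when comparing permuted to observed statistics


class DesignError(ValueError):
    """The sample design cannot support the requested computation."""


@dataclass
class TIConfig:
    """Thresholds and test settings for the translatome analysis.

    ``fold_cutoff`` is a linear fold change: a gene is deregulated when
    |log2 TI| >= log2(fold_cutoff) and its FDR < ``alpha``.
    ``expression_min_mean`` is the normalized-count floor a gene must
    reach in all four (fraction, condition) groups to count as expressed.
    """

    fold_cutoff: float = 1.5
    alpha: float = 0.05
    expression_min_mean: float = 10.0
    n_permutations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.expression_min_mean <= 0 or self.n_permutations <= 0:
            raise ValueError("expression_min_mean and n_permutations must be positive")

    @property
    def log2_cutoff(self) -> float:
        return float(np.log2(self.fold_cutoff))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame | CountDataset) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median over genes of count / geometric
    mean across samples; genes with a zero in any sample are excluded
    from the median (their geometric mean would vanish).
    """
    if isinstance(counts, CountDataset):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise DesignError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference"
        )
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    log_factors = np.median(logs - log_geomean[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean of factors -> 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def normalized_counts(dataset: CountDataset,
                      size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = estimate_size_factors(dataset)
    return dataset.counts / size_factors


def group_means(dataset: CountDataset, normalized: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene mean normalized count of each (fraction, condition) group.

    Columns: cyto_NT, cyto_T, poly_NT, poly_T.
    """
    if normalized is None:
        normalized = normalized_counts(dataset)
    out = {}
    for frac, tag in (("cytoplasmic", "cyto"), ("polysomal", "poly")):
        for cond in ("NT", "T"):
            cols = dataset.columns_for(frac, cond)
            out[f"{tag}_{cond}"] = normalized[cols].mean(axis=1)
    return pd.DataFrame(out)


def filter_expressed(dataset: CountDataset, cfg: TIConfig,
                     normalized: pd.DataFrame | None = None) -> pd.Index:
    """Genes whose normalized mean reaches the floor in all four groups."""
    means = group_means(dataset, normalized)
    keep = (means >= cfg.expression_min_mean).all(axis=1)
    if not keep.any():
        import logging

        logging.getLogger("polyti").warning("expression filter removed every gene")
    return means.index[keep]


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def compute_ti(dataset: CountDataset, genes: Sequence[str] | pd.Index | None = None,
               normalized: pd.DataFrame | None = None) -> pd.DataFrame:
    """x1, x2 and log2 TI per gene on normalized group means.

    Genes with a zero group mean get NaN (flagged, never +-inf); the
    expression filter normally guarantees positivity.
    """
    means = group_means(dataset, normalized)
    if genes is not None:
        means = means.loc[list(genes)]
    with np.errstate(divide="ignore", invalid="ignore"):
        x1 = means["poly_T"] / means["cyto_T"]
        x2 = means["poly_NT"] / means["cyto_NT"]
        log2_ti = np.log2(x1 / x2)
    log2_ti = log2_ti.where(np.isfinite(log2_ti))
    return pd.DataFrame({"x1": x1, "x2": x2, "log2_ti": log2_ti})


# ---------------------------------------------------------------------------
# permutation machinery (shared with regclass)
# ---------------------------------------------------------------------------

def _require_replicates(dataset: CountDataset, fractions: Sequence[str]) -> None:
    for frac in fractions:
        for cond in ("NT", "T"):
            n = len(dataset.columns_for(frac, cond))
            if n < 2:
                raise DesignError(
                    f"group ({frac}, {cond}) has {n} replicate(s); >= 2 required"
                )


def _exhaustive_masks(n: int, k: int) -> np.ndarray:
    """All C(n, k) boolean masks selecting which of n columns are 'T'."""
    masks = np.zeros((comb(n, k), n), dtype=bool)
    for i, idx in enumerate(combinations(range(n), k)):
        masks[i, list(idx)] = True
    return masks


def _log_ratio(matrix: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """log2(mean over mask cols) - log2(mean over complement), per assignment.

    matrix: (genes, cols); masks: (A, cols) boolean.  Returns (genes, A).
    Zero means yield -+inf, which count as extreme in the tail comparison.
    """
    k = masks[0].sum()
    w_t = masks.T.astype(float) / k
    w_nt = (~masks).T.astype(float) / (masks.shape[1] - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(matrix @ w_t) - np.log2(matrix @ w_nt)


def _identity_mask(is_t: np.ndarray) -> int:
    """Row index of the observed labelling within _exhaustive_masks order."""
    masks = _exhaustive_masks(len(is_t), int(is_t.sum()))
    hit = np.nonzero((masks == is_t).all(axis=1))[0]
    return int(hit[0])


def interaction_permutation_pvalues(
    norm_cyto: np.ndarray,
    cyto_is_t: np.ndarray,
    norm_poly: np.ndarray,
    poly_is_t: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Two-sided permutation p-values for the log2 TI interaction statistic.

    Condition labels are permuted independently within each fraction; the
    distinct relabellings form the cross-product of the two within-fraction
    label assignments.  When that product is <= ``n_permutations`` the
    null distribution is enumerated exhaustively and
    p = #{|stat_perm| >= |stat_obs|} / n_distinct (the identity
    relabelling is part of the enumeration, so p is never 0); otherwise
    Monte-Carlo with p = (1 + #extreme) / (1 + n_permutations).
    """
    nc, kc = len(cyto_is_t), int(cyto_is_t.sum())
    np_, kp = len(poly_is_t), int(poly_is_t.sum())
    n_distinct = comb(nc, kc) * comb(np_, kp)

    if n_distinct <= n_permutations:
        masks_c = _exhaustive_masks(nc, kc)
        masks_p = _exhaustive_masks(np_, kp)
        lr_c = _log_ratio(norm_cyto, masks_c)  # (genes, Ac)
        lr_p = _log_ratio(norm_poly, masks_p)  # (genes, Ap)
        obs = np.abs(
            lr_p[:, _identity_mask(poly_is_t)] - lr_c[:, _identity_mask(cyto_is_t)]
        )
        count = np.zeros(norm_cyto.shape[0], dtype=np.int64)
        for j in range(lr_c.shape[1]):  # chunk over cytoplasmic assignments
            diff = np.abs(lr_p - lr_c[:, [j]])
            count += (diff >= obs[:, None] - _TOL).sum(axis=1)
        return count / n_distinct

    rng = np.random.default_rng([seed, 17])
    obs = np.abs(
        _log_ratio(norm_poly, poly_is_t[None, :])[:, 0]
        - _log_ratio(norm_cyto, cyto_is_t[None, :])[:, 0]
    )
    count = np.zeros(norm_cyto.shape[0], dtype=np.int64)
    done = 0
    chunk = max(1, min(n_permutations, 2_000_000 // max(norm_cyto.shape[0], 1)))
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        masks_c = np.stack([rng.permutation(cyto_is_t) for _ in range(b)])
        masks_p = np.stack([rng.permutation(poly_is_t) for _ in range(b)])
        stat = _log_ratio(norm_poly, masks_p) - _log_ratio(norm_cyto, masks_c)
        count += (np.abs(stat) >= obs[:, None] - _TOL).sum(axis=1)
        done += b
    return (1 + count) / (1 + n_permutations)


def difference_permutation_pvalues(
    norm: np.ndarray,
    is_t: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Two-sided permutation p-values for a single-fraction log2 fold change."""
    n, k = len(is_t), int(is_t.sum())
    n_distinct = comb(n, k)
    if n_distinct <= n_permutations:
        masks = _exhaustive_masks(n, k)
        lr = _log_ratio(norm, masks)
        obs = np.abs(lr[:, _identity_mask(is_t)])
        count = (np.abs(lr) >= obs[:, None] - _TOL).sum(axis=1)
        return count / n_distinct
    rng = np.random.default_rng([seed, 19])
    obs = np.abs(_log_ratio(norm, is_t[None, :])[:, 0])
    masks = np.stack([rng.permutation(is_t) for _ in range(n_permutations)])
    lr = _log_ratio(norm, masks)
    count = (np.abs(lr) >= obs[:, None] - _TOL).sum(axis=1)
    return (1 + count) / (1 + n_permutations)


def test_ti(dataset: CountDataset, genes: Sequence[str] | pd.Index,
            cfg: TIConfig, normalized: pd.DataFrame | None = None) -> pd.Series:
    """Permutation p-value of the TI interaction for each gene."""
    _require_replicates(dataset, ("cytoplasmic", "polysomal"))
    if normalized is None:
        normalized = normalized_counts(dataset)
    genes = list(genes)
    cyto_cols = dataset.columns_for("cytoplasmic")
    poly_cols = dataset.columns_for("polysomal")
    cyto_is_t = (dataset.sheet.loc[cyto_cols, "condition"] == "T").to_numpy()
    poly_is_t = (dataset.sheet.loc[poly_cols, "condition"] == "T").to_numpy()
    p = interaction_permutation_pvalues(
        normalized.loc[genes, cyto_cols].to_numpy(),
        cyto_is_t,
        normalized.loc[genes, poly_cols].to_numpy(),
        poly_is_t,
        cfg.n_permutations,
        cfg.seed,
    )
    return pd.Series(p, index=pd.Index(genes, name="gene_id"), name="p_value")


def adjust_fdr(p_values: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-free)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        out = arr
    else:
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="fdr")
    return out


def classify_translational(records: pd.DataFrame, cfg: TIConfig) -> pd.Series:
    """up / down / stable from log2_ti and fdr columns per the fold/alpha rule."""
    log2_ti = records["log2_ti"]
    fdr = records["fdr"]
    cut = cfg.log2_cutoff
    cls = np.where(
        (fdr < cfg.alpha) & (log2_ti >= cut),
        "up",
        np.where((fdr < cfg.alpha) & (log2_ti <= -cut), "down", "stable"),
    )
    return pd.Series(cls, index=records.index, name="te_class")


def run_translatome(dataset: CountDataset, cfg: TIConfig) -> pd.DataFrame:
    """Full pipeline: normalize, filter, TI, permutation test, FDR, classes.

    Returns one row per expressed gene with columns x1, x2, log2_ti,
    p_value, fdr, te_class.
    """
    normalized = normalized_counts(dataset)
    genes = filter_expressed(dataset, cfg, normalized)
    table = compute_ti(dataset, genes, normalized)
    table["p_value"] = test_ti(dataset, genes, cfg, normalized)
    table["fdr"] = adjust_fdr(table["p_value"])
    table["te_class"] = classify_translational(table, cfg)
    table.index.name = "gene_id"
    return table
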