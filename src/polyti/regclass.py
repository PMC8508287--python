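"""Transcriptional classification and translational x transcriptional cross-tables.

Transcriptional regulation is read from the cytoplasmic fractions alone:
per gene, log2 fold change of treated over non-treated normalized means,
a condition-label permutation test within the cytoplasmic samples,
BH-FDR, and the same fold / alpha thresholds as the translational
classifier.  `cross_classify` then tabulates the two 3-way classifications
against each other, reporting counts and row percentages (percent of each
translational-class row).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from polyti.io import CountDataset
from polyti.translatome import (
    TIConfig,
    _require_replicates,
    adjust_fdr,
    difference_permutation_pvalues,
    normalized_counts,
)

CLASS_ORDER = ("up", "down", "stable")


@dataclass
class RegClassTable:
    """3x3 contingency of translational (rows) x transcriptional (columns) classes.

    ``row_percentages`` are percent of each row total, to 1 decimal; rows
    with zero total carry NaN (reported as not-available).
    """

    counts: pd.DataFrame
    row_percentages: pd.DataFrame

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def classify_transcriptional(dataset: CountDataset, genes: Sequence[str] | pd.Index,
                             cfg: TIConfig) -> pd.DataFrame:
    """Per-gene cytoplasmic log2FC, permutation p, FDR and txn_class."""
    _require_replicates(dataset, ("cytoplasmic",))
    normalized = normalized_counts(dataset)
    genes = list(genes)
    cols = dataset.columns_for("cytoplasmic")
    is_t = (dataset.sheet.loc[cols, "condition"] == "T").to_numpy()
    sub = normalized.loc[genes, cols]
    mean_t = sub.loc[:, np.asarray(cols)[is_t]].mean(axis=1)
    mean_nt = sub.loc[:, np.asarray(cols)[~is_t]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_t / mean_nt)
    log2fc = log2fc.where(np.isfinite(log2fc))
    p = difference_permutation_pvalues(
        sub.to_numpy(), is_t, cfg.n_permutations, cfg.seed
    )
    out = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p}, index=pd.Index(genes, name="gene_id")
    )
    out["fdr"] = adjust_fdr(out["p_value"])
    cut = cfg.log2_cutoff
    out["txn_class"] = np.where(
        (out["fdr"] < cfg.alpha) & (out["log2fc"] >= cut),
        "up",
        np.where((out["fdr"] < cfg.alpha) & (out["log2fc"] <= -cut), "down", "stable"),
    )
    return out


def cross_classify(te_classes: pd.Series | Mapping[str, str],
                   txn_classes: pd.Series | Mapping[str, str],
                   universe: Sequence[str] | pd.Index) -> RegClassTable:
    """Cross-tabulate the two classifications over ``universe``.

    Every gene of the universe must carry both classes; row percentages
    are percent of the translational-class row total, to 1 decimal.
    """
    te = pd.Series(te_classes)
    txn = pd.Series(txn_classes)
    universe = pd.Index(universe)
    for name, series in (("translational", te), ("transcriptional", txn)):
        missing = universe.difference(series.index)
        if len(missing):
            raise KeyError(
                f"gene(s) missing a {name} class: {list(missing[:5])}"
            )
    te = te.loc[universe]
    txn = txn.loc[universe]
    counts = (
        pd.crosstab(te, txn)
        .reindex(index=CLASS_ORDER, columns=CLASS_ORDER, fill_value=0)
        .astype(int)
    )
    counts.index.name = "te_class"
    counts.columns.name = "txn_class"
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    return RegClassTable(counts=counts, row_percentages=pct.round(1))


def class_percentages(counts: Sequence[int], total: int) -> list[float]:
    """Each count as a percent of ``total``, to 2 decimals.

    ``total`` must equal the sum of the counts; a zero total yields NaN
    markers (not-available).
    """
    counts = [int(c) for c in counts]
    if total == 0:
        return [float("nan")] * len(counts)
    if total != sum(counts):
        raise ValueError(f"total {total} does not equal sum of counts {sum(counts)}")
    return [round(100.0 * c / total, 2) for c in counts]
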