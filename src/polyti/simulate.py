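"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a replicated polysome-profiling RNA-seq design:
four groups {cytoplasmic, polysomal} x {NT, T}, negative-binomial counts
with per-sample library-size factors, per-gene transcriptional log2
fold-changes and translational-efficiency (TE) shifts drawn from 3-class
mixtures (up / down / stable), plus matching 5'UTR sequences (TOP or
non-TOP) and Hill-curve dose-response surfaces with optional injected
synergy.  The per-gene expected count is

    mu(g, s) = base_mean_g * sizefactor_s * 2^(txn_lfc_g * [T])
               * rho(fraction_s) * 2^(te_lfc_g * [T and polysomal])

with NB variance mu + alpha * mu^2 (alpha = per-gene dispersion) and
rho the polysome-loading factor (cytoplasmic rho = 1).  The TE shift
therefore moves only the treated polysomal group, which is exactly the
interaction the translational index measures.

Default mixture weights echo a translatome in which ~6% of expressed
genes are translationally deregulated, three-quarters of those downward,
and TOP mRNAs concentrate in the translationally up-regulated class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from polyti.io import CountDataset, DoseMatrix, UTRRecord

CLASSES = ("up", "down", "stable")

_PYRIMIDINES = np.array(list("CT"))
_PURINES = np.array(list("AG"))
_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth regulation state of one simulated gene."""

    gene_id: str
    txn_class: str
    txn_log2fc: float
    te_class: str
    te_log2fc: float
    base_mean: float
    dispersion: float
    is_top: bool

    def __post_init__(self) -> None:
        if (self.te_log2fc == 0.0) != (self.te_class == "stable"):
            raise ConfigError(f"{self.gene_id}: te_log2fc/te_class inconsistent")
        if (self.txn_log2fc == 0.0) != (self.txn_class == "stable"):
            raise ConfigError(f"{self.gene_id}: txn_log2fc/txn_class inconsistent")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ConfigError(f"{self.gene_id}: base_mean and dispersion must be > 0")


@dataclass
class SimConfig:
    """Knobs of the generator; ``seed`` is mandatory.

    Class proportions are (up, down, stable) simplexes.  Effect
    magnitudes |log2fc| are uniform on ``effect_range`` (log2 units);
    dispersions and library-size factors uniform on their ranges;
    base means log-normal.  ``top_prevalence_te_up`` /
    ``top_prevalence_elsewhere`` give the probability that a gene
    carries a 5'TOP UTR depending on its TE class.
    """

    n_genes: int = 2000
    replicates: int = 3
    txn_proportions: tuple[float, float, float] = (0.024, 0.024, 0.952)
    te_proportions: tuple[float, float, float] = (0.015, 0.047, 0.938)
    effect_range: tuple[float, float] = (0.7, 2.5)
    dispersion_range: tuple[float, float] = (0.05, 0.2)
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    base_mean_log_mean: float = 6.0
    base_mean_log_sd: float = 1.0
    polysome_loading: float = 0.8
    top_prevalence_te_up: float = 0.25
    top_prevalence_elsewhere: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("SimConfig.seed is mandatory")
        if self.n_genes <= 0 or self.replicates <= 0:
            raise ConfigError("n_genes and replicates must be positive")
        for name, props in (("txn", self.txn_proportions), ("te", self.te_proportions)):
            if len(props) != 3 or any(p < 0 for p in props):
                raise ConfigError(f"{name}_proportions must be 3 non-negative values")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ConfigError(f"{name}_proportions must sum to 1")
        for name, rng in (
            ("effect_range", self.effect_range),
            ("dispersion_range", self.dispersion_range),
            ("size_factor_range", self.size_factor_range),
        ):
            lo, hi = rng
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be a positive (lo, hi) with hi >= lo")
        if self.polysome_loading <= 0:
            raise ConfigError("polysome_loading must be > 0")
        for p in (self.top_prevalence_te_up, self.top_prevalence_elsewhere):
            if not 0 <= p <= 1:
                raise ConfigError("TOP prevalences must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stage (truth=0, counts=1, utrs=2...)."""
        return np.random.default_rng([int(self.seed), stream])


def simulate_gene_truth(config: SimConfig) -> list[GeneTruth]:
    """Draw per-gene regulation classes, effect sizes, and TOP labels."""
    rng = config.rng(0)
    n = config.n_genes
    txn_cls = rng.choice(CLASSES, size=n, p=config.txn_proportions)
    te_cls = rng.choice(CLASSES, size=n, p=config.te_proportions)
    lo, hi = config.effect_range

    def effects(classes: np.ndarray) -> np.ndarray:
        mag = rng.uniform(lo, hi, size=n)
        sign = np.where(classes == "up", 1.0, np.where(classes == "down", -1.0, 0.0))
        return mag * sign

    txn_lfc = effects(txn_cls)
    te_lfc = effects(te_cls)
    base_mean = rng.lognormal(config.base_mean_log_mean, config.base_mean_log_sd, size=n)
    disp = rng.uniform(*config.dispersion_range, size=n)
    p_top = np.where(
        te_cls == "up", config.top_prevalence_te_up, config.top_prevalence_elsewhere
    )
    is_top = rng.random(n) < p_top
    width = len(str(n))
    return [
        GeneTruth(
            gene_id=f"g{i + 1:0{width}d}",
            txn_class=str(txn_cls[i]),
            txn_log2fc=float(txn_lfc[i]),
            te_class=str(te_cls[i]),
            te_log2fc=float(te_lfc[i]),
            base_mean=float(base_mean[i]),
            dispersion=float(disp[i]),
            is_top=bool(is_top[i]),
        )
        for i in range(n)
    ]


def _sample_sheet(replicates: int) -> pd.DataFrame:
    rows = []
    for frac, tag in (("cytoplasmic", "cyto"), ("polysomal", "poly")):
        for cond in ("NT", "T"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tag}_{cond}_{rep}",
                        "fraction": frac,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(truth: Sequence[GeneTruth], config: SimConfig) -> CountDataset:
    """Negative-binomial counts for the 2x2 (fraction x condition) design.

    Dispersion alpha parameterizes variance mu + alpha mu^2; alpha below
    1e-8 falls back to Poisson draws for numerical stability.
    """
    if not truth:
        raise ConfigError("truth must be nonempty")
    rng = config.rng(1)
    sheet = _sample_sheet(config.replicates)
    size_factors = rng.uniform(*config.size_factor_range, size=len(sheet))

    base = np.array([g.base_mean for g in truth])
    txn = np.array([g.txn_log2fc for g in truth])
    te = np.array([g.te_log2fc for g in truth])
    alpha = np.array([g.dispersion for g in truth])

    counts = np.empty((len(truth), len(sheet)), dtype=np.int64)
    for j, (sample_id, row) in enumerate(sheet.iterrows()):
        treated = row["condition"] == "T"
        poly = row["fraction"] == "polysomal"
        mu = base * size_factors[j]
        if treated:
            mu = mu * np.exp2(txn)
        if poly:
            mu = mu * config.polysome_loading
            if treated:
                mu = mu * np.exp2(te)
        nb = alpha >= 1e-8
        col = np.empty(len(truth), dtype=np.int64)
        if nb.any():
            size = 1.0 / alpha[nb]
            p = size / (size + mu[nb])
            col[nb] = rng.negative_binomial(size, p)
        if (~nb).any():
            col[~nb] = rng.poisson(mu[~nb])
        counts[:, j] = col
    frame = pd.DataFrame(counts, index=[g.gene_id for g in truth], columns=sheet.index)
    return CountDataset(counts=frame, sheet=sheet)


def simulate_utrs(truth: Sequence[GeneTruth], seed: int) -> list[UTRRecord]:
    """5'UTRs consistent with each gene's TOP label.

    TOP genes: cap-adjacent C, then 4-15 further pyrimidines, then a
    G-rich stretch.  Non-TOP genes either start with a purine or carry a
    pyrimidine run shorter than the TOP minimum.  Lengths 20-200 nt.
    """
    if not truth:
        raise ConfigError("truth must be nonempty")
    rng = np.random.default_rng([int(seed), 2])
    records = []
    for g in truth:
        length = int(rng.integers(20, 201))
        if g.is_top:
            run = int(rng.integers(4, 16))  # pyrimidines after the initial C
            head = "C" + "".join(rng.choice(_PYRIMIDINES, size=run))
            g_rich = "".join(rng.choice(_BASES, size=10, p=[0.1, 0.1, 0.7, 0.1]))
            tail_len = max(length - len(head) - len(g_rich), 0)
            seq = head + g_rich + "".join(rng.choice(_BASES, size=tail_len))
        else:
            if rng.random() < 0.5:
                head = str(rng.choice(_PURINES))
            else:
                run = int(rng.integers(0, 4))  # < 4 extra pyrimidines: below minimum
                head = "C" + "".join(rng.choice(_PYRIMIDINES, size=run)) + str(
                    rng.choice(_PURINES)
                )
            tail_len = max(length - len(head), 0)
            seq = head + "".join(rng.choice(_BASES, size=tail_len))
        records.append(UTRRecord(g.gene_id, seq))
    return records


def simulate_dose_surface(
    hill_a,
    hill_b,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    synergy_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseMatrix:
    """Dose surface whose margins follow the given Hill curves exactly and
    whose interior is the Loewe-expected effect plus ``synergy_offset``
    (negative = deeper inhibition than additivity = synergy) plus noise.
    """
    from polyti.synergy import hill_effect, loewe_expected

    rng = np.random.default_rng([int(seed), 3])
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    resp = np.empty((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            if da == 0 and db == 0:
                resp[i, j] = (hill_a.e0 + hill_b.e0) / 2.0
            elif db == 0:
                resp[i, j] = hill_effect(da, hill_a)
            elif da == 0:
                resp[i, j] = hill_effect(db, hill_b)
            else:
                resp[i, j] = loewe_expected(da, db, hill_a, hill_b) + synergy_offset
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return DoseMatrix(doses_a, doses_b, resp)


def write_truth_table(truth: Sequence[GeneTruth], path: str | Path) -> None:
    pd.DataFrame([vars(g) for g in truth]).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
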