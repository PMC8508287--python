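"""5'TOP motif calling, reference-catalogue overlap, and set enrichment.

A 5'-terminal oligopyrimidine (TOP) mRNA begins with a cap-adjacent C
followed by a run of pyrimidines, often trailed by a G-rich stretch.
The scanner calls a UTR TOP when position 1 is C and the maximal
pyrimidine (C/T) run starting there is at least 5 bases long (the C plus
at least 4 more); runs longer than the textbook ~15 are still TOP — the
upper bound is soft.  The downstream G-richness is reported but never
gates the call.  Overlap with a reference TOP catalogue is summarized as
disjoint Venn counts over a gene universe and tested for
over-representation with the hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from polyti.io import UTRRecord

_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class TOPCall:
    """Scanner decision for one 5'UTR."""

    gene_id: str
    is_top: bool
    pyrimidine_run: int
    g_rich_downstream: bool
    reason: str


def scan_top_motif(utr: UTRRecord, min_run: int = 5, g_window: int = 10) -> TOPCall:
    """Call the TOP motif on one UTR (position 1 = cap-adjacent base)."""
    seq = utr.sequence
    run = 0
    for base in seq:
        if base in _PYRIMIDINES:
            run += 1
        else:
            break
    window = seq[run : run + g_window]
    g_rich = bool(window) and window.count("G") / len(window) >= 0.5
    if seq[0] == "N":
        return TOPCall(utr.gene_id, False, 0, g_rich, "first base is N (ambiguous)")
    if seq[0] != "C":
        return TOPCall(
            utr.gene_id, False, run, g_rich, f"first base is {seq[0]}, not C"
        )
    if run < min_run:
        return TOPCall(
            utr.gene_id,
            False,
            run,
            g_rich,
            f"pyrimidine run {run} shorter than minimum {min_run}",
        )
    return TOPCall(utr.gene_id, True, run, g_rich, f"C + {run - 1} further pyrimidines")


def scan_all(utrs: Iterable[UTRRecord], min_run: int = 5) -> pd.DataFrame:
    calls = [scan_top_motif(u, min_run=min_run) for u in utrs]
    return pd.DataFrame([vars(c) for c in calls]).set_index("gene_id")


def overlap_counts(set_a: Iterable[str], reference: Iterable[str],
                   universe: Iterable[str]) -> tuple[int, int, int, int]:
    """Disjoint Venn counts (only_a, only_ref, both, neither) over a universe."""
    set_a, reference, universe = set(set_a), set(reference), set(universe)
    for name, members in (("set_a", set_a), ("reference", reference)):
        outside = members - universe
        if outside:
            raise ValueError(
                f"{name} member(s) outside the universe: {sorted(outside)[:5]}"
            )
    both = len(set_a & reference)
    only_a = len(set_a - reference)
    only_ref = len(reference - set_a)
    neither = len(universe) - both - only_a - only_ref
    return only_a, only_ref, both, neither


def enrichment_test(both: int, only_a: int, only_ref: int, neither: int,
                    alternative: str = "greater") -> float:
    """Over-representation p-value for the overlap of set A with the reference.

    One-sided (default): hypergeometric upper tail P(X >= both) drawing
    |A| genes from a universe containing |reference| successes.
    ``alternative='two-sided'`` uses Fisher's exact test on the 2x2 table.
    """
    for name, v in (("both", both), ("only_a", only_a),
                    ("only_ref", only_ref), ("neither", neither)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if alternative == "two-sided":
        return float(
            fisher_exact([[both, only_a], [only_ref, neither]], alternative="two-sided")[1]
        )
    if alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    population = both + only_a + only_ref + neither
    successes = both + only_ref
    draws = both + only_a
    return float(hypergeom.sf(both - 1, population, successes, draws))


def annotate_top(ti_table: pd.DataFrame,
                 calls: pd.DataFrame | Mapping[str, bool] | Sequence[str]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach an ``is_top`` column to a TI table and summarize TOP fractions.

    ``calls`` may be a scanner table (with an ``is_top`` column), a
    gene -> bool mapping, or a plain reference gene list (membership =
    TOP).  Genes without a call get NA and are excluded from fractions.
    Returns the annotated table and the TOP fraction per
    (te_class, txn_class) cell present in the table (te_class alone when
    no txn_class column exists).
    """
    table = ti_table.copy()
    if isinstance(calls, pd.DataFrame):
        membership = calls["is_top"]
    elif isinstance(calls, Mapping):
        membership = pd.Series(dict(calls))
    else:
        top_set = set(calls)
        membership = pd.Series({g: g in top_set for g in table.index})
    table["is_top"] = table.index.map(membership.to_dict())

    known = table.dropna(subset=["is_top"])
    by = [c for c in ("te_class", "txn_class") if c in known.columns]
    if by:
        fractions = (
            known.groupby(by, observed=False)["is_top"]
            .agg(n_genes="size", n_top="sum")
            .reset_index()
        )
        fractions["top_fraction"] = np.where(
            fractions["n_genes"] > 0,
            fractions["n_top"] / fractions["n_genes"],
            np.nan,
        )
    else:
        fractions = pd.DataFrame(
            {
                "n_genes": [len(known)],
                "n_top": [int(known["is_top"].sum())],
                "top_fraction": [known["is_top"].mean() if len(known) else np.nan],
            }
        )
    return table, fractions
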