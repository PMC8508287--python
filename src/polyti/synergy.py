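"""Loewe-additivity synergy scoring for drug-combination dose matrices.

Monotherapy responses are modelled with a four-parameter Hill curve

    E(d) = einf + (e0 - einf) / (1 + (d / ec50)^h)

on effects expressed as fraction of untreated control (1 = no effect).
Loewe additivity predicts the combination effect E at doses (a, b) as
the solution of the dose-equivalence equation

    a / D_A(E) + b / D_B(E) = 1

where D_X(E) is the monotherapy dose of drug X alone producing effect E
(the closed-form Hill inverse).  The synergy score of an observed
surface is 100 * (expected - observed) per dose pair: for
inhibition-type effects a positive score means the combination
suppresses growth/viability more deeply than additivity predicts
(synergy), zero is additive, negative is antagonism.  A sham
combination of a drug with itself scores zero everywhere by the
dose-equivalence identity, which the test suite verifies numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from polyti.io import DoseMatrix

_BISECT_TOL = 1e-9
_FLAT_VARIANCE = 1e-12


class UnreachableEffect(ValueError):
    """The requested effect lies outside the open (einf, e0) range of a curve."""


class SynergyError(ValueError):
    """The dose matrix cannot be scored (e.g. missing zero-dose margins)."""


@dataclass(frozen=True)
class HillParams:
    """Four-parameter Hill curve; ``e0`` effect at zero dose (control = 1),
    ``einf`` asymptote at infinite dose, ``ec50`` midpoint dose, ``h`` slope."""

    e0: float
    einf: float
    ec50: float
    h: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.h <= 0:
            raise ValueError("ec50 and h must be > 0")


def hill_effect(dose: float | np.ndarray, params: HillParams) -> float | np.ndarray:
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / params.ec50) ** params.h, 0.0)
    out = params.einf + (params.e0 - params.einf) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def fit_hill(doses: Sequence[float], responses: Sequence[float],
             n_starts: int = 8) -> tuple[HillParams, dict]:
    """Bounded least-squares Hill fit with multi-start over EC50 seeds.

    Requires >= 4 dose points including dose 0; responses normalized to
    control = 1.  Bounds: e0 in [0.8, 1.2], einf in [0, 1.2],
    h in [0.1, 10].  A flat response raises the ``degenerate`` flag
    (curve unusable for the Loewe inverse).  Returns the parameters and
    a diagnostics dict with the residual sum of squares.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 4:
        raise ValueError("need >= 4 dose points to fit a Hill curve")
    if 0.0 not in doses:
        raise ValueError("dose 0 (untreated control) must be included")
    if responses.var() < _FLAT_VARIANCE:
        params = HillParams(
            e0=float(np.clip(responses.mean(), 0.8, 1.2)),
            einf=float(np.clip(responses.mean(), 0.0, 1.2)),
            ec50=float(max(doses.max(), 1.0)),
            h=1.0,
            degenerate=True,
        )
        return params, {"rss": float(np.sum((responses - responses.mean()) ** 2)),
                        "degenerate": True}

    positive = doses[doses > 0]
    lo = np.log10(positive.min() / 10.0)
    hi = np.log10(positive.max() * 10.0)
    ec50_seeds = np.logspace(lo, hi, n_starts)

    def residuals(theta: np.ndarray) -> np.ndarray:
        e0, einf, log_ec50, h = theta
        p = HillParams(e0=e0, einf=einf, ec50=10.0 ** log_ec50, h=h)
        return hill_effect(doses, p) - responses

    bounds = ([0.8, 0.0, lo - 1, 0.1], [1.2, 1.2, hi + 1, 10.0])
    best = None
    for seed in ec50_seeds:
        x0 = np.array(
            [
                np.clip(responses[doses == 0].mean(), 0.8, 1.2),
                np.clip(responses[np.argmax(doses)], 0.0, 1.2),
                np.log10(seed),
                1.0,
            ]
        )
        try:
            sol = least_squares(residuals, x0, bounds=bounds)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    e0, einf, log_ec50, h = best.x
    params = HillParams(e0=float(e0), einf=float(einf),
                        ec50=float(10.0 ** log_ec50), h=float(h))
    rss = float(2.0 * best.cost)
    return params, {"rss": rss, "degenerate": False}


def inverse_hill(effect: float, params: HillParams) -> float:
    """Closed-form dose producing ``effect``; round-trips with the forward curve.

    The effect must lie strictly between e0 and einf, otherwise the
    effect is unreachable by this drug alone and the caller applies the
    infinite-dose convention.
    """
    if params.degenerate:
        raise UnreachableEffect("degenerate (flat) curve has no usable inverse")
    lo, hi = sorted((params.e0, params.einf))
    if not lo < effect < hi:
        raise UnreachableEffect(
            f"effect {effect} outside the open interval ({lo}, {hi})"
        )
    return params.ec50 * ((params.e0 - effect) / (effect - params.einf)) ** (1.0 / params.h)


def _equivalent_dose_ratio(dose: float, effect: float, params: HillParams) -> float:
    """dose / D(effect), treating unreachable-deep effects as ratio 0."""
    if dose == 0.0:
        return 0.0
    try:
        return dose / inverse_hill(effect, params)
    except UnreachableEffect:
        lo = min(params.e0, params.einf)
        if effect <= lo:
            return 0.0  # deeper than this drug can go alone: equivalent dose -> inf
        raise


def loewe_expected(dose_a: float, dose_b: float,
                   hill_a: HillParams, hill_b: HillParams) -> float:
    """Loewe-additive expected effect at a dose pair, by bisection on E.

    Margins reduce exactly to the corresponding monotherapy curve; the
    pair (0, 0) returns the (mean) zero-dose effect.  The combination
    equation is solved to 1e-9 in E.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be >= 0")
    if hill_a.degenerate or hill_b.degenerate:
        raise SynergyError("cannot form Loewe expectation from a degenerate fit")
    if dose_a == 0.0 and dose_b == 0.0:
        return (hill_a.e0 + hill_b.e0) / 2.0
    if dose_b == 0.0:
        return float(hill_effect(dose_a, hill_a))
    if dose_a == 0.0:
        return float(hill_effect(dose_b, hill_b))

    def f(effect: float) -> float:
        return (
            _equivalent_dose_ratio(dose_a, effect, hill_a)
            + _equivalent_dose_ratio(dose_b, effect, hill_b)
            - 1.0
        )

    lo = min(hill_a.einf, hill_b.einf) + 1e-12
    hi = min(hill_a.e0, hill_b.e0) - 1e-12
    if hi <= lo:
        raise SynergyError("curves leave no effect interval to search")
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0:
        return lo  # combination saturates at the deepest attainable effect
    if f_hi < 0:
        raise SynergyError(
            f"no root bracketed for doses ({dose_a}, {dose_b}); "
            "inputs appear non-monotone"
        )
    # f is increasing in E: larger effect (closer to e0) means smaller
    # equivalent doses and larger ratios
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < _BISECT_TOL:
            break
    return 0.5 * (lo + hi)


@dataclass
class SynergySurface:
    """Observed vs Loewe-expected effects with per-cell scores and verdicts."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    score: np.ndarray  # 100 * (expected - observed); positive = synergy
    verdict: np.ndarray  # 'synergy' | 'additive' | 'antagonism'
    hill_a: HillParams | None = None
    hill_b: HillParams | None = None

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = pd.Index(self.doses_a, name="dose_a")
        cols = pd.Index(self.doses_b, name="dose_b")
        return {
            name: pd.DataFrame(getattr(self, name), index=idx, columns=cols)
            for name in ("observed", "expected", "score", "verdict")
        }


def synergy_score(observed: DoseMatrix,
                  hill_a: HillParams | None = None,
                  hill_b: HillParams | None = None,
                  verdict_threshold: float = 5.0) -> SynergySurface:
    """Score a dose surface against its Loewe-additive expectation.

    Monotherapy Hill curves are fitted from the surface's own zero-dose
    margins unless supplied.  Score = 100 * (expected - observed)
    percentage points of control; |score| below ``verdict_threshold``
    is called additive.
    """
    if not observed.has_zero_margins:
        raise SynergyError(
            "dose matrix lacks zero-dose margins; monotherapy curves cannot "
            "be anchored, refusing to score"
        )
    if hill_a is None:
        hill_a, diag_a = fit_hill(observed.doses_a, observed.response[:, 0])
        if diag_a["degenerate"]:
            raise SynergyError("drug A margin is flat; Loewe inverse undefined")
    if hill_b is None:
        hill_b, diag_b = fit_hill(observed.doses_b, observed.response[0, :])
        if diag_b["degenerate"]:
            raise SynergyError("drug B margin is flat; Loewe inverse undefined")

    expected = np.empty_like(observed.response)
    for i, da in enumerate(observed.doses_a):
        for j, db in enumerate(observed.doses_b):
            expected[i, j] = loewe_expected(da, db, hill_a, hill_b)
    score = 100.0 * (expected - observed.response)
    verdict = np.where(
        score > verdict_threshold,
        "synergy",
        np.where(score < -verdict_threshold, "antagonism", "additive"),
    )
    return SynergySurface(
        doses_a=observed.doses_a,
        doses_b=observed.doses_b,
        observed=observed.response,
        expected=expected,
        score=score,
        verdict=verdict,
        hill_a=hill_a,
        hill_b=hill_b,
    )


def replicate_score_test(surfaces: Sequence[SynergySurface]) -> pd.DataFrame:
    """One-sample t-statistic per dose pair across replicate surfaces.

    Returns a long table (dose_a, dose_b, mean_score, t, p_value, fdr)
    with BH adjustment across cells; requires >= 2 replicates.
    """
    from scipy.stats import ttest_1samp

    from polyti.translatome import adjust_fdr

    if len(surfaces) < 2:
        raise SynergyError("replicate testing needs >= 2 surfaces")
    scores = np.stack([s.score for s in surfaces])
    first = surfaces[0]
    rows = []
    for i, da in enumerate(first.doses_a):
        for j, db in enumerate(first.doses_b):
            cell = scores[:, i, j]
            t, p = ttest_1samp(cell, 0.0)
            rows.append(
                {"dose_a": da, "dose_b": db, "mean_score": cell.mean(),
                 "t": float(t), "p_value": float(p)}
            )
    table = pd.DataFrame(rows)
    table["fdr"] = adjust_fdr(table["p_value"].to_numpy())
    return table


def plot_score_contour(surface: SynergySurface, path: str) -> None:
    """Contour plot of the synergy-score surface (positive = synergy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(surface.doses_b, surface.doses_a, surface.score, cmap="RdBu_r")
    fig.colorbar(cs, ax=ax, label="Loewe synergy score (points of control)")
    ax.set_xlabel("dose of drug B")
    ax.set_ylabel("dose of drug A")
    ax.set_title("Loewe synergy / antagonism")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
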