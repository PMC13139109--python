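"""Single-case treatment-effect evaluation.

Tau-U combines a Mann-Whitney-type cross-phase dominance statistic with
Kendall trend corrections inside each phase.  For phases A (earlier) and
B (later):

* ``S_AB``     = sum over all cross pairs of ``sign(B_j - A_i)``
* ``S_trendA`` = Kendall S of phase A (within-phase monotone trend)
* ``S_trendB`` = Kendall S of phase B

The reported variant "A vs. B + Trend B - Trend A" uses
``S = S_AB + S_trendB - S_trendA`` with denominator
``nA nB + nB(nB-1)/2 + nA(nA-1)/2``; simpler variants drop the trend
terms.  ``SD_S`` is the additive null standard deviation of S (the three
components are pairwise uncorrelated under an exchangeable null), and the
z-test is two-sided normal.  Ties contribute zero to every S.

Visual-analysis metrics (phase means/SDs/slopes, between-phase overlap,
last-5-vs-first-5 immediacy) and the Brief Pain Inventory
minimal-important-difference flag (change >= 0.87 on the 0-10 scale)
complete the evaluation battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .ema import EMASeries, PHASES, interpolate_missing

__all__ = [
    "TauUResult",
    "VisualMetrics",
    "PhaseContrast",
    "tau_u",
    "evaluate_sced",
    "visual_metrics",
    "bpi_change",
    "effect_band",
    "VARIANTS",
]

VARIANTS = ("AvsB", "AvsB+TrendB", "AvsB+TrendB-TrendA")

BPI_MID = 0.87  # minimal important difference on the 0-10 BPI scale
HIGH_OVERLAP = 30.0  # percent


@dataclass
class TauUResult:
    variant: str
    S_AB: int
    S_trendA: int
    S_trendB: int
    S_total: int
    denominator: int
    tau: float
    SD_S: float
    z: float
    p: float

    def __post_init__(self) -> None:
        assert abs(self.tau) <= 1 + 1e-12
        assert self.SD_S > 0


def _kendall_S(x: np.ndarray) -> int:
    diffs = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diffs, 1).sum())


def tau_u(phase_a, phase_b, variant: str = "AvsB+TrendB-TrendA") -> TauUResult:
    """Tau-U for one phase contrast (A earlier, B later)."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 3 or nb < 3:
        raise ValueError(f"phases too short for Tau-U (nA={na}, nB={nb}; need >= 3)")
    S_AB = int(np.sign(b[None, :] - a[:, None]).sum())
    S_tA = _kendall_S(a)
    S_tB = _kendall_S(b)

    use_tB = "TrendB" in variant
    use_tA = "TrendA" in variant
    S = S_AB + (S_tB if use_tB else 0) - (S_tA if use_tA else 0)
    denom = na * nb + (nb * (nb - 1) // 2 if use_tB else 0) + (na * (na - 1) // 2 if use_tA else 0)
    var = na * nb * (na + nb + 1) / 3.0
    if use_tA:
        var += na * (na - 1) * (2 * na + 5) / 18.0
    if use_tB:
        var += nb * (nb - 1) * (2 * nb + 5) / 18.0
    sd = sqrt(var)
    z = S / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return TauUResult(
        variant=variant, S_AB=S_AB, S_trendA=S_tA, S_trendB=S_tB,
        S_total=S, denominator=denom, tau=S / denom, SD_S=sd, z=z, p=min(p, 1.0),
    )


def effect_band(tau: float) -> str:
    """Interpretation bands for |Tau-U|: <0.2 small, 0.2-0.6 moderately
    high, 0.6-0.8 high, >0.8 very high."""
    a = abs(tau)
    if a < 0.2:
        return "small"
    if a < 0.6:
        return "moderately high"
    if a <= 0.8:
        return "high"
    return "very high"


CONTRASTS = (("baseline", "phase1"), ("baseline", "phase2"), ("phase1", "phase2"))


def evaluate_sced(
    series: EMASeries,
    outcome_items,
    handling: str = "interpolate",
    variant: str = "AvsB+TrendB-TrendA",
) -> pd.DataFrame:
    """Tau-U per contrast per outcome with the chosen missing-data rule.

    ``handling='interpolate'`` fills missing values (phase-bounded linear
    interpolation) before the analysis; ``'exclude'`` drops them.  Each
    intervention phase is one SCED phase.  Returns a tidy table with the
    Tau-U components, p-value, significance stars and interpretation band.
    """
    if handling not in ("interpolate", "exclude"):
        raise ValueError("handling must be 'interpolate' or 'exclude'")
    present = set(series.phase.unique())
    missing_phases = [ph for ph in PHASES if ph not in present]
    if missing_phases:
        raise ValueError(f"series lacks phase(s) {missing_phases}")
    work = interpolate_missing(series) if handling == "interpolate" else series
    rows = []
    for item in outcome_items:
        col = work.data[item]
        for pa, pb in CONTRASTS:
            a = col[(work.phase == pa).to_numpy()].dropna().to_numpy()
            b = col[(work.phase == pb).to_numpy()].dropna().to_numpy()
            r = tau_u(a, b, variant)
            stars = "**" if r.p < 0.01 else ("*" if r.p < 0.05 else "")
            rows.append({
                "outcome": item, "contrast": f"{pa}-{pb}",
                "tau": r.tau, "SD_S": r.SD_S, "z": r.z, "p": r.p,
                "sig": stars, "band": effect_band(r.tau),
                "S_AB": r.S_AB, "S_trendA": r.S_trendA, "S_trendB": r.S_trendB,
                "nA": len(a), "nB": len(b), "handling": handling,
            })
    return pd.DataFrame(rows)


@dataclass
class PhaseContrast:
    earlier: str
    later: str
    overlap_percent: float
    high_overlap: bool
    immediacy: float | None  # |mean(last 5 of earlier) - mean(first 5 of later)|


@dataclass
class VisualMetrics:
    item: str
    phase_stats: pd.DataFrame  # index phase; columns mean, sd, slope, n
    contrasts: list[PhaseContrast]


def visual_metrics(series: EMASeries, item: str) -> VisualMetrics:
    """Phase descriptives plus overlap and immediacy for each contrast.

    Overlap is the share of later-phase points inside the earlier phase's
    [min, max] range; a flag marks overlap above 30%.  Immediacy compares
    the mean of the last five points of the earlier phase with the first
    five of the later phase, and is undefined (None) when either phase
    has fewer than five points.
    """
    stats_rows = {}
    values = {}
    for ph in PHASES:
        mask = (series.phase == ph).to_numpy()
        y = series.data.loc[mask, item].dropna()
        values[ph] = y
        t = np.asarray(y.index, dtype=float)
        slope = np.nan
        if len(y) >= 2 and np.ptp(t) > 0:
            slope = float(np.polyfit(t, y.to_numpy(), 1)[0])
        stats_rows[ph] = dict(mean=float(y.mean()) if len(y) else np.nan,
                              sd=float(y.std(ddof=1)) if len(y) > 1 else np.nan,
                              slope=slope, n=len(y))
    contrasts = []
    for pa, pb in CONTRASTS:
        a, b = values[pa].to_numpy(), values[pb].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        inside = (b >= a.min()) & (b <= a.max())
        overlap = 100.0 * inside.mean()
        if len(a) >= 5 and len(b) >= 5:
            immediacy = float(abs(a[-5:].mean() - b[:5].mean()))
        else:
            immediacy = None
        contrasts.append(PhaseContrast(pa, pb, overlap, overlap > HIGH_OVERLAP, immediacy))
    return VisualMetrics(item=item,
                         phase_stats=pd.DataFrame(stats_rows).T[["mean", "sd", "slope", "n"]],
                         contrasts=contrasts)


def bpi_change(pre: float, post: float) -> dict:
    """Minimal-important-difference flags for a BPI interference change.

    Improvement fires when ``pre - post >= 0.87``; worsening when
    ``post - pre >= 0.87``.  Scores must lie on the 0-10 scale.
    """
    for name, v in (("pre", pre), ("post", post)):
        if not (0.0 <= v <= 10.0):
            raise ValueError(f"{name} score {v} outside [0, 10]")
    change = pre - post
    return {
        "change": change,
        "improved": change >= BPI_MID,
        "worsened": -change >= BPI_MID,
    }
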