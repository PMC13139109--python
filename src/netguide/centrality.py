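"""Delta-time effect matrices and continuous-time centrality indices.

At lag ``delta`` the effect of node j on node i is ``Phi(delta)[i, j]``
with ``Phi = expm(A delta)`` (convention pinned: ``A[i, j]`` is the effect
of j on i, so centralities are column sums over receivers).

Total effect centrality (TEC) of node j sums its lagged effects on every
other node; indirect effect centrality (IEC) is the part transmitted
through mediators: the direct effect keeps only A's diagonal plus the
single entry ``A[i, j]`` when propagating j -> i, and the indirect effect
is the remainder.  The treatment outcome is always a receiver but never a
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .ctvar import DriftModel, FitResult

__all__ = [
    "CentralityTable",
    "effect_matrix",
    "tec",
    "iec",
    "centrality_profile",
    "centrality_intervals",
    "rank_candidates",
]

CT_KINDS = ("TEC", "IEC")


@dataclass
class CentralityTable:
    kind: str
    delta: float | None
    point: pd.Series  # index = candidate nodes
    lo: pd.Series | None = None
    hi: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.lo is not None:
            bad = (self.lo > self.point + 1e-12) | (self.hi < self.point - 1e-12)
            if bad.any():
                raise ValueError("interval must bracket the point estimate")

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(self.point.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"node": self.point.index, "index": self.kind,
                           "delta": self.delta, "point": self.point.to_numpy()})
        df["lo"] = self.lo.to_numpy() if self.lo is not None else np.nan
        df["hi"] = self.hi.to_numpy() if self.hi is not None else np.nan
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def effect_matrix(model: DriftModel | np.ndarray, delta: float) -> np.ndarray:
    """``Phi(delta) = expm(A delta)``; entry [i, j] is j's lagged effect on i."""
    A = model.A if isinstance(model, DriftModel) else np.asarray(model, dtype=float)
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if np.max(np.real(np.linalg.eigvals(A))) >= 0:
        raise ValueError("unstable drift matrix")
    return linalg.expm(A * delta)


def _candidates(names, outcome):
    return [n for n in names if n != outcome]


def _tec_values(A: np.ndarray, delta: float) -> np.ndarray:
    Phi = effect_matrix(A, delta)
    return Phi.sum(axis=0) - np.diag(Phi)  # column sums over receivers i != j


def _iec_values(A: np.ndarray, delta: float) -> np.ndarray:
    p = A.shape[0]
    Phi = effect_matrix(A, delta)
    IE = np.zeros((p, p))
    diag = np.diag(np.diag(A))
    for j in range(p):
        for i in range(p):
            if i == j:
                continue
            Atil = diag.copy()
            Atil[i, j] = A[i, j]
            DE = linalg.expm(Atil * delta)[i, j]
            IE[i, j] = Phi[i, j] - DE
    return IE.sum(axis=0)


def tec(model: DriftModel, delta: float, outcome: str | None = None) -> CentralityTable:
    """Total effect centrality at lag ``delta``: ``TEC_j = sum_{i!=j} Phi[i, j]``.

    All nodes (the outcome included) count as receivers; candidates are
    the process nodes only.
    """
    vals = pd.Series(_tec_values(model.A, delta), index=list(model.names))
    return CentralityTable("TEC", delta, vals.loc[_candidates(model.names, outcome)])


def iec(model: DriftModel, delta: float, outcome: str | None = None) -> CentralityTable:
    """Indirect effect centrality: total minus single-path direct effects."""
    vals = pd.Series(_iec_values(model.A, delta), index=list(model.names))
    return CentralityTable("IEC", delta, vals.loc[_candidates(model.names, outcome)])


_KIND_FN = {"TEC": _tec_values, "IEC": _iec_values}


def centrality_profile(
    model: DriftModel, deltas, kind: str = "TEC", outcome: str | None = None
) -> list[CentralityTable]:
    """Evaluate TEC or IEC over a grid of delta-times."""
    fn = tec if kind == "TEC" else iec
    return [fn(model, float(d), outcome) for d in deltas]


def centrality_intervals(
    fit: FitResult, delta: float, kind: str = "TEC", outcome: str | None = None
) -> CentralityTable:
    """Point centrality with a 50% (25th-75th percentile) bootstrap interval.

    The interval summarizes the spread of the index across the parametric
    bootstrap replicate drift matrices stored on the fit.
    """
    if not fit.replicates:
        raise ValueError("fit carries no bootstrap replicates; rerun fit_ctvar with bootstrap>0")
    fn = _KIND_FN[kind]
    names = list(fit.model.names)
    point = pd.Series(fn(fit.model.A, delta), index=names)
    reps = np.array([fn(A, delta) for A in fit.replicates])
    lo = pd.Series(np.percentile(reps, 25, axis=0), index=names)
    hi = pd.Series(np.percentile(reps, 75, axis=0), index=names)
    cand = _candidates(names, outcome)
    # the interval describes replicate spread; widen to include the point
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    return CentralityTable(kind, delta, point.loc[cand], lo.loc[cand], hi.loc[cand])


def rank_candidates(table: CentralityTable, model: DriftModel | None = None,
                    outcome: str | None = None) -> list[str]:
    """Candidates ordered most-central first.

    Ties on the point estimate break by the same index at twice the
    delta-time, then lexicographically — a fully deterministic order.
    """
    point = table.point
    if model is not None and table.delta:
        fn = _KIND_FN.get(table.kind, _tec_values)
        wide = pd.Series(fn(model.A, 2.0 * table.delta), index=list(model.names))
        wide = wide.loc[list(point.index)]
    else:
        wide = pd.Series(0.0, index=point.index)
    order = sorted(point.index, key=lambda n: (-point[n], -wide[n], n))
    return list(order)
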