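"""Discrete-time (graphical) VAR alternatives.

Workflow mirrors the common graphical-VAR practice for EMA data: detrend
each item (OLS on clock time), transform margins to normal scores, fit a
lag-1 VAR on within-day consecutive occasion pairs only (no overnight
lags), and read the contemporaneous network off the residual precision
matrix K as partial correlations ``rho[i, j] = -K[i, j] / sqrt(K_ii K_jj)``.

The penalized path uses L1 node-wise regressions for the temporal part
and the graphical lasso for the precision, both selected by EBIC (weight
gamma, default 0.5) over a 50-point log-spaced penalty grid with min/max
ratio 0.01.  The unpenalized path uses ordinary least squares and the
inverse sample covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import GraphicalLasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

__all__ = [
    "ContempNetwork",
    "DTCentralityTable",
    "detrend_and_transform",
    "fit_dtvar",
    "dt_centrality",
    "strongest_edge_to_outcome",
]

N_GRID = 50
GRID_RATIO = 0.01


@dataclass
class ContempNetwork:
    names: tuple[str, ...]
    pcor: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]
    penalized: bool
    alpha: float | None = None  # selected penalty (penalized path)

    def __post_init__(self) -> None:
        P = np.asarray(self.pcor, dtype=float)
        if not np.allclose(P, P.T, atol=1e-8):
            raise ValueError("partial-correlation matrix must be symmetric")
        if not np.allclose(np.diag(P), 1.0, atol=1e-8):
            raise ValueError("partial-correlation matrix must have unit diagonal")
        if np.any(np.abs(P) > 1 + 1e-8):
            raise ValueError("partial correlations must lie in [-1, 1]")
        self.pcor = 0.5 * (P + P.T)

    @property
    def p(self) -> int:
        return len(self.names)

    def edge(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.pcor[i, j])

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"node_i": self.names[i], "node_j": self.names[j], "weight": self.pcor[i, j]}
            for i in range(self.p) for j in range(i + 1, self.p)
        ]
        return pd.DataFrame(rows)


@dataclass
class DTCentralityTable:
    table: pd.DataFrame  # index candidate node; columns strength, expected_influence, betweenness, closeness

    def __post_init__(self) -> None:
        t = self.table
        if np.any(t["strength"] + 1e-10 < t["expected_influence"].abs()):
            raise ValueError("strength must dominate |expected influence|")
        if np.any(t["betweenness"] < 0):
            raise ValueError("betweenness must be non-negative")


# ---------------------------------------------------------------------------
# preprocessing


def normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based normal-scores transform ``Phi^{-1}((rank - 0.5) / n)``.

    Depends on the data only through ranks, so any strictly monotone
    re-expression of the input leaves the output unchanged.
    """
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    z = np.full_like(x, np.nan)
    ranks = stats.rankdata(x[obs], method="average")
    z[obs] = stats.norm.ppf((ranks - 0.5) / obs.sum())
    return z


def detrend_and_transform(series) -> pd.DataFrame:
    """Remove an OLS linear trend in clock time per item, then apply the
    rank-based normal-scores transform ``z = Phi^{-1}((rank - 0.5) / n)``.

    Output columns have zero empirical slope and near-Gaussian margins;
    the transform is invariant to strictly monotone re-expression of a
    column.  Constant (or perfectly linear, hence constant-residual)
    items are an error.
    """
    df = series if isinstance(series, pd.DataFrame) else series.data
    t = np.asarray(df.index, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 occasions per item")
    X = np.column_stack([np.ones_like(t), t])
    out = {}
    for col in df.columns:
        y = df[col].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        resid = y - X @ beta
        r = resid[obs]
        if np.nanstd(r) < 1e-10 or len(np.unique(np.round(r, 12))) < 3:
            raise ValueError(f"item {col!r} is constant after detrending; cannot transform")
        z = np.full_like(y, np.nan)
        z[obs] = normal_scores(r)
        out[col] = z
    return pd.DataFrame(out, index=df.index)


def _day_index(t: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(t, dtype=float) / 24.0).astype(int)


def _consecutive_pairs(t: np.ndarray, days: np.ndarray | None) -> np.ndarray:
    """Indices k such that occasion k+1 follows k within the same day."""
    days = _day_index(t) if days is None else days
    return np.nonzero(days[1:] == days[:-1])[0]


# ---------------------------------------------------------------------------
# EBIC model selection helpers


def _ebic_glasso(S: np.ndarray, n: int, gamma: float) -> tuple[np.ndarray, float]:
    """Graphical lasso over the log-spaced penalty grid, EBIC-selected."""
    p = S.shape[0]
    amax = np.max(np.abs(S - np.diag(np.diag(S))))
    amax = max(amax, 1e-3)
    grid = np.geomspace(GRID_RATIO * amax, amax, N_GRID)
    best = (np.inf, None, None)
    for alpha in grid[::-1]:  # sparse to dense; warm starts not needed at this size
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gl = GraphicalLasso(alpha=float(alpha), covariance="precomputed",
                                    max_iter=200).fit(S)
        except FloatingPointError:
            continue
        K = gl.precision_
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            continue
        ll = 0.5 * n * (logdet - np.trace(S @ K))
        E = np.count_nonzero(np.triu(K, 1))
        ebic = -2 * ll + E * np.log(n) + 4 * E * gamma * np.log(p)
        if ebic < best[0]:
            best = (ebic, K, float(alpha))
    if best[1] is None:
        raise ValueError("graphical lasso failed on the whole penalty grid")
    return best[1], best[2]


def _ebic_lasso_row(X: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """L1 regression for one temporal row, EBIC-selected over the grid."""
    n, p = X.shape
    amax = np.max(np.abs(X.T @ y)) / n
    amax = max(amax, 1e-6)
    grid = np.geomspace(GRID_RATIO * amax, amax, N_GRID)
    best = (np.inf, np.zeros(p))
    for alpha in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            coef = Lasso(alpha=float(alpha), fit_intercept=False,
                         max_iter=5000).fit(X, y).coef_
        rss = np.sum((y - X @ coef) ** 2)
        k = np.count_nonzero(coef)
        ebic = n * np.log(max(rss, 1e-12) / n) + k * np.log(n) + 2 * gamma * k * np.log(p)
        if ebic < best[0]:
            best = (ebic, coef)
    return best[1]


# ---------------------------------------------------------------------------
# model fitting


def _pcor_from_precision(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return np.clip(0.5 * (P + P.T), -1.0, 1.0)


def fit_dtvar(
    residuals: pd.DataFrame,
    penalized: bool = True,
    gamma: float = 0.5,
    days: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ContempNetwork]:
    """Lag-1 VAR on within-day consecutive pairs + contemporaneous network.

    ``residuals`` is the detrended/transformed table (time-indexed in
    hours).  Returns the temporal coefficient matrix B (row = receiver)
    and the partial-correlation network of the VAR residuals.
    """
    names = tuple(residuals.columns)
    p = len(names)
    if p < 2:
        raise ValueError("need at least two nodes")
    t = np.asarray(residuals.index, dtype=float)
    Z = residuals.to_numpy(dtype=float)
    pairs = _consecutive_pairs(t, days)
    keep = ~np.isnan(Z[pairs]).any(axis=1) & ~np.isnan(Z[pairs + 1]).any(axis=1)
    pairs = pairs[keep]
    if len(pairs) < p + 2:
        raise ValueError(f"only {len(pairs)} usable within-day pairs; need more occasions")
    X0, X1 = Z[pairs], Z[pairs + 1]

    if penalized:
        B = np.vstack([_ebic_lasso_row(X0, X1[:, i], gamma) for i in range(p)])
        resid = X1 - X0 @ B.T
        S = np.cov(resid.T, bias=True)
        K, alpha = _ebic_glasso(S, len(pairs), gamma)
    else:
        B_t, *_ = np.linalg.lstsq(X0, X1, rcond=None)
        B = B_t.T
        resid = X1 - X0 @ B.T
        S = np.cov(resid.T, bias=True)
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "singular residual covariance in the unpenalized path; try penalized=True"
            )
        K, alpha = np.linalg.inv(S), None

    temporal = pd.DataFrame(B, index=list(names), columns=list(names))
    net = ContempNetwork(names=names, pcor=_pcor_from_precision(K),
                         penalized=penalized, alpha=alpha)
    return temporal, net


# ---------------------------------------------------------------------------
# centrality


def _graph(network: ContempNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(network.names)
    for i in range(network.p):
        for j in range(i + 1, network.p):
            w = network.pcor[i, j]
            if abs(w) > 1e-12:
                G.add_edge(network.names[i], network.names[j],
                           weight=abs(w), signed=w, length=1.0 / abs(w))
    return G


def dt_centrality(network: ContempNetwork, outcome: str | None = None) -> DTCentralityTable:
    """Strength, expected influence, betweenness and closeness per node.

    Strength is the absolute edge-weight sum and expected influence the
    signed sum.  Betweenness and closeness use edge length ``1/|rho|`` on
    the nonzero-edge graph; closeness is ``1 / sum(shortest distances)``
    (0 for nodes that cannot reach every other node).  Candidates exclude
    the outcome.
    """
    G = _graph(network)
    p = network.p
    strength = {n: 0.0 for n in network.names}
    ei = {n: 0.0 for n in network.names}
    for a, b, d in G.edges(data=True):
        strength[a] += d["weight"]
        strength[b] += d["weight"]
        ei[a] += d["signed"]
        ei[b] += d["signed"]
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    close = {}
    for n in network.names:
        dists = nx.single_source_dijkstra_path_length(G, n, weight="length")
        if len(dists) < p:  # cannot reach some node
            close[n] = 0.0
        else:
            total = sum(v for k, v in dists.items() if k != n)
            close[n] = 1.0 / total if total > 0 else 0.0
    rows = pd.DataFrame(
        {"strength": strength, "expected_influence": ei,
         "betweenness": btw, "closeness": close}
    ).loc[list(network.names)]
    if outcome is not None:
        rows = rows.drop(index=outcome)
    return DTCentralityTable(rows)


def strongest_edge_to_outcome(network, outcome: str) -> str | None:
    """Process node with the largest-magnitude edge to the outcome.

    Accepts a :class:`ContempNetwork` (contemporaneous edge weights) or a
    ``(matrix, names)`` pair / DriftModel-like effect matrix where row
    ``outcome`` holds the lagged effects onto the outcome.  Returns
    ``None`` when every edge to the outcome is zero.  Ties break
    lexicographically.
    """
    if isinstance(network, ContempNetwork):
        names = list(network.names)
        i = names.index(outcome)
        weights = {n: network.pcor[i, names.index(n)] for n in names if n != outcome}
    else:
        M, names = network
        names = list(names)
        i = names.index(outcome)
        M = np.asarray(M, dtype=float)
        weights = {n: M[i, names.index(n)] for n in names if n != outcome}
    best = sorted(weights, key=lambda n: (-abs(weights[n]), n))
    if abs(weights[best[0]]) <= 1e-12:
        return None
    return best[0]
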