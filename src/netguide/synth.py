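"""Synthetic EMA generator with known network ground truth.

Emulates the study design: 5 prompts/day at 8, 11, 14, 17 and 20 h with a
uniform 0-3 h response jitter, one once-daily item slot per day, a 14-20
day baseline followed by two ~2-week intervention phases, sporadic
missingness, and phase-onset intervention effects on targeted facets.

The six inflexibility facets and the interference outcome evolve as a
7-node Ornstein-Uhlenbeck network with a planted centrality ordering:
one facet (lack of present-moment awareness) is a hub with the strongest
outgoing couplings, making its composite (awareness) the planted
most-central node and openness the least central.  A projected 4-node
composite-level model accompanies the facet-level truth so guidance can
be evaluated exactly.

Interventions enter as constant inputs on the targeted facets' equations
(ramped linearly over a few days), so the outcome responds only through
the network couplings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from . import centrality as ct
from .ctvar import DriftModel, simulate_ctvar
from .ema import COMPOSITES, EMASeries, ItemRegistry, default_registry
from .guidance import GuidanceConfig, guide_treatment

__all__ = [
    "Schedule",
    "InterventionEffect",
    "SyntheticTruth",
    "PROMPT_HOURS",
    "make_schedule",
    "default_truth",
    "uniform_truth",
    "default_interventions",
    "simulate_ema",
    "recovery_experiment",
]

PROMPT_HOURS = (8.0, 11.0, 14.0, 17.0, 20.0)
RESPONSE_WINDOW_H = 3.0


@dataclass
class Schedule:
    """A realized assessment schedule: jittered response times with phase
    labels and a per-day once-daily item slot."""

    timestamps: np.ndarray  # hours since study start, strictly increasing
    phase: np.ndarray  # phase label per occasion
    once_daily: np.ndarray  # bool, True where the extra item is delivered
    days: tuple[int, int, int]

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.timestamps) > 0)

    def n_occasions(self) -> int:
        return len(self.timestamps)

    def median_interval(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


def make_schedule(
    baseline_days: int,
    phase1_days: int = 14,
    phase2_days: int = 14,
    seed: int | None = None,
    jitter: bool = True,
    prompt_hours: tuple[float, ...] = PROMPT_HOURS,
) -> Schedule:
    """Realize the prompt schedule: 5 jittered occasions/day, one of which
    (the first) carries the once-daily item."""
    if not (14 <= baseline_days <= 20):
        raise ValueError("baseline length must be 14-20 days")
    rng = np.random.default_rng(seed)
    times, phases, extra = [], [], []
    day = 0
    for phase, ndays in zip(("baseline", "phase1", "phase2"),
                            (baseline_days, phase1_days, phase2_days)):
        for _ in range(ndays):
            base = 24.0 * day + np.asarray(prompt_hours)
            j = rng.uniform(0.0, RESPONSE_WINDOW_H, size=len(prompt_hours)) if jitter else 0.0
            t = base + j
            times.append(t)
            phases.extend([phase] * len(prompt_hours))
            extra.extend([True] + [False] * (len(prompt_hours) - 1))
            day += 1
    return Schedule(
        timestamps=np.concatenate(times),
        phase=np.asarray(phases),
        once_daily=np.asarray(extra, dtype=bool),
        days=(baseline_days, phase1_days, phase2_days),
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class InterventionEffect:
    phase: str  # 'phase1' | 'phase2'
    facets: tuple[str, ...]  # facet codes targeted
    shift: float  # nominal equilibrium reduction of each targeted facet (scale units)
    ramp_days: float = 3.0


@dataclass
class SyntheticTruth:
    model7: DriftModel  # 6 facets + interference
    model4: DriftModel  # 3 composites + interference (projection of model7)
    delta: float  # delta-time (h) at which the ordering is planted
    planted: dict  # mcni/lcni composites and facets
    interventions: list[InterventionEffect] = field(default_factory=list)
    missingness: float = 0.05  # per-occasion probability of a missed prompt
    motivation_coef: tuple[float, float, float] = (95.0, -0.9, 6.0)  # a + b*mean(facets) + noise sd
    pain_coef: tuple[float, float, float] = (8.0, 0.85, 6.0)  # a + b*interference + noise sd
    clip_log: dict = field(default_factory=dict)

    def sidecar(self) -> dict:
        return {
            "names7": list(self.model7.names),
            "A7": self.model7.A.tolist(),
            "mu7": self.model7.mu.tolist(),
            "Q7": self.model7.Q.tolist(),
            "R7": self.model7.R.tolist(),
            "names4": list(self.model4.names),
            "A4": self.model4.A.tolist(),
            "delta": self.delta,
            "planted": self.planted,
            "missingness": self.missingness,
            "interventions": [
                dict(phase=iv.phase, facets=list(iv.facets),
                     shift=iv.shift, ramp_days=iv.ramp_days)
                for iv in self.interventions
            ],
        }

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2))


def _aggregate(model7: DriftModel, registry: ItemRegistry) -> DriftModel:
    """Composite-level model by projection: A4 = L A7 L+, Q4 = L Q7 L',
    mu4 = L mu7 (L averages each facet pair, passes the outcome through)."""
    names7 = list(model7.names)
    outcome = registry.outcome
    L = np.zeros((4, 7))
    for ci, comp in enumerate(COMPOSITES):
        for m in registry.composite_members(comp):
            L[ci, names7.index(m)] = 0.5
    L[3, names7.index(outcome)] = 1.0
    Lp = np.linalg.pinv(L)
    A4 = L @ model7.A @ Lp
    Q4 = L @ model7.Q @ L.T
    R4 = L ** 2 @ model7.R
    return DriftModel(
        names=tuple(list(COMPOSITES) + [outcome]),
        A=A4, mu=L @ model7.mu, Q=0.5 * (Q4 + Q4.T), R=R4,
    )


#: Outgoing coupling strength per facet code: lack of present-moment
#: awareness is the hub; the openness facets are weakest so openness is
#: the planted least-central composite (fusion weakest within it).
_OUT_COUPLING = {
    "LPMA": 0.140,
    "SAC": 0.040,
    "LV": 0.050,
    "Inaction": 0.030,
    "EA": 0.016,
    "Fusion": 0.008,
}
_DECAY = 0.50  # 1/h; autocorrelation ~ exp(-0.5 * 3h) = 0.22 at the median gap
_OUTCOME_FEEDBACK = 0.015  # interference -> facets
_DIFFUSION_SD = 18.0  # stationary scale of each node (approx, 0-100 units)
_NOISE_SD = 5.0  # measurement noise SD


def default_truth(
    registry: ItemRegistry | None = None,
    missingness: float = 0.05,
    couplings: dict | None = None,
    require_strict: bool = True,
) -> SyntheticTruth:
    """The planted-hub ground truth used throughout tests and analyses."""
    registry = registry or default_registry()
    outcome = registry.outcome
    facet_items = list(registry.facet_items)
    names = tuple([it.name for it in facet_items] + [outcome])
    p = len(names)
    coup = dict(_OUT_COUPLING)
    if couplings:
        coup.update(couplings)
    A = np.full((p, p), 0.0)
    for j, it in enumerate(facet_items):
        A[:, j] = coup[it.facet]
    A[:, p - 1] = _OUTCOME_FEEDBACK  # outcome feeds back weakly onto facets
    np.fill_diagonal(A, -_DECAY)
    mu = np.array([30.0, 35.0, 40.0, 38.0, 36.0, 42.0, 50.0])
    Q = 2.0 * _DECAY * _DIFFUSION_SD ** 2 * np.eye(p)
    R = np.full(p, _NOISE_SD ** 2)
    model7 = DriftModel(names=names, A=A, mu=mu, Q=Q, R=R)
    model7.require_stable()
    model4 = _aggregate(model7, registry)
    model4.require_stable()

    delta = 3.0  # median inter-prompt gap of the study schedule
    comp_rank = ct.rank_candidates(ct.tec(model4, delta, outcome=outcome),
                                   model=model4, outcome=outcome)
    facet_rank = ct.rank_candidates(ct.tec(model7, delta, outcome=outcome),
                                    model=model7, outcome=outcome)
    mcni, lcni = comp_rank[0], comp_rank[-1]

    def facet_order(comp):
        members = registry.composite_members(comp)
        return [n for n in facet_rank if n in members]

    tec4 = ct.tec(model4, delta, outcome=outcome).point
    tec7 = ct.tec(model7, delta, outcome=outcome).point
    if require_strict and (tec4.round(12).duplicated().any()
                           or tec7.round(12).duplicated().any()):
        raise ValueError("planted centrality ordering is not strict")
    planted = {
        "mcni_composite": mcni,
        "lcni_composite": lcni,
        "composite_ranking": comp_rank,
        "mcni_facet": facet_order(mcni)[0],
        "lcni_facet": facet_order(lcni)[-1],
        "facet_ranking": facet_rank,
    }
    return SyntheticTruth(model7=model7, model4=model4, delta=delta,
                          planted=planted, missingness=missingness)


def uniform_truth(registry: ItemRegistry | None = None,
                  missingness: float = 0.05) -> SyntheticTruth:
    """Null variant: all facets share one coupling, so no composite is
    genuinely more central (selection should be at chance)."""
    registry = registry or default_registry()
    coup = {code: 0.05 for code in _OUT_COUPLING}
    truth = default_truth(registry, missingness, couplings=coup, require_strict=False)
    truth.planted["null"] = True
    return truth


def default_interventions(truth: SyntheticTruth, registry: ItemRegistry | None = None,
                          order: str = "MCNI-first", shift: float = 15.0,
                          ramp_days: float = 3.0) -> list[InterventionEffect]:
    """Phase-onset effects targeting the planted MCNI composite's facets in
    one phase and the LCNI composite's in the other."""
    registry = registry or default_registry()
    mc = truth.planted["mcni_composite"]
    lc = truth.planted["lcni_composite"]
    first, second = (mc, lc) if order == "MCNI-first" else (lc, mc)

    def codes(comp):
        return tuple(registry[m].facet for m in registry.composite_members(comp))

    return [
        InterventionEffect("phase1", codes(first), shift, ramp_days),
        InterventionEffect("phase2", codes(second), shift, ramp_days),
    ]


# ---------------------------------------------------------------------------
# simulation


def _input_path(truth: SyntheticTruth, registry: ItemRegistry,
                schedule: Schedule) -> np.ndarray | None:
    """Piecewise-constant forcing per gap: for each targeted facet j an
    input c_j = shift * |a_jj| * ramp(t), evaluated at gap midpoints."""
    if not truth.interventions:
        return None
    names = list(truth.model7.names)
    t = schedule.timestamps
    mid = 0.5 * (t[:-1] + t[1:])
    c = np.zeros((len(mid), len(names)))
    phase_start = {ph: t[schedule.phase == ph][0]
                   for ph in np.unique(schedule.phase)}
    for iv in truth.interventions:
        if iv.phase not in phase_start:
            continue
        t0 = phase_start[iv.phase]
        ramp = np.clip((mid - t0) / (iv.ramp_days * 24.0), 0.0, 1.0)
        ramp[mid < t0] = 0.0
        # effects persist for the rest of the study once ramped in
        for code in iv.facets:
            j = names.index(registry.facet_name(code))
            c[:, j] += -iv.shift * abs(truth.model7.A[j, j]) * ramp
    return c


def simulate_ema(
    truth: SyntheticTruth,
    schedule: Schedule,
    seed: int | None = None,
    registry: ItemRegistry | None = None,
) -> tuple[EMASeries, dict]:
    """Sample an EMA dataset from the ground truth at the schedule's times.

    The 7-node latent path is sampled exactly; measurement noise is added;
    motivation and pain-intensity items are noisy affine reads of the
    latent state (motivation once daily); values are clipped to [0, 100]
    (clipping rate logged); whole occasions go missing with probability
    ``truth.missingness``.  Returns the series and the truth sidecar.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    inputs = _input_path(truth, registry, schedule)
    latent = simulate_ctvar(truth.model7, schedule.timestamps,
                            seed=int(rng.integers(2 ** 31)), inputs=inputs)
    facet_names = [it.name for it in registry.facet_items]
    data = latent.copy()

    a, b, s = truth.motivation_coef
    motiv = a + b * latent[facet_names].mean(axis=1) + s * rng.standard_normal(len(latent))
    a2, b2, s2 = truth.pain_coef
    pain = a2 + b2 * latent[registry.outcome] + s2 * rng.standard_normal(len(latent))
    motivation_item = registry.role_items("motivation")[0]
    pain_item = registry.role_items("pain-intensity")[0]
    data[motivation_item] = motiv
    data[pain_item] = pain
    data.loc[~schedule.once_daily, motivation_item] = np.nan

    raw = data.to_numpy()
    n_clip = int(np.sum((raw < 0) | (raw > 100)))
    truth.clip_log = {"clipped": n_clip, "total": int(np.isfinite(raw).sum())}
    data = data.clip(0.0, 100.0)

    miss = rng.random(len(data)) < truth.missingness
    data.loc[miss] = np.nan

    order = [n for n in registry.names if n in data.columns]
    series = EMASeries(
        participant="synthetic",
        data=data[order],
        phase=pd.Series(schedule.phase, index=data.index),
    )
    return series, truth.sidecar()


# ---------------------------------------------------------------------------
# centrality-recovery experiment


def recovery_experiment(
    n_replicates: int = 100,
    occasions: int = 150,
    seed: int | None = None,
    truth: SyntheticTruth | None = None,
    use_truth_matrix: bool = False,
    config: GuidanceConfig | None = None,
    registry: ItemRegistry | None = None,
) -> dict:
    """Does two-stage guidance recover the planted centrality ordering?

    Per replicate: simulate a baseline-only series of roughly
    ``occasions`` occasions, run stage-1 guidance (CT-VAR fit on the
    composites, unless ``use_truth_matrix`` scores the generating
    composite model directly), and record whether the selected MCNI/LCNI
    composites match the planted ones plus the Kendall rank concordance
    of the composite TEC ordering.
    """
    from scipy.stats import kendalltau

    registry = registry or default_registry()
    truth = truth or default_truth(registry)
    config = config or GuidanceConfig(measurement_noise="zero", stage2=False,
                                      min_occasions=30)
    rng = np.random.default_rng(seed)
    outcome = registry.outcome
    days = int(np.clip(ceil(occasions / len(PROMPT_HOURS)), 14, None))
    true_rank = truth.planted["composite_ranking"]
    true_scores = ct.tec(truth.model4, truth.delta, outcome=outcome).point

    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2 ** 31))
        sched = make_schedule(min(days, 20), max(days - 20, 0) or 1, 1, seed=rep_seed)
        # keep only the first `occasions` occasions, relabelled as baseline
        sched = Schedule(
            timestamps=sched.timestamps[:occasions],
            phase=np.asarray(["baseline"] * occasions),
            once_daily=sched.once_daily[:occasions],
            days=(days, 0, 0),
        )
        baseline_truth = SyntheticTruth(
            model7=truth.model7, model4=truth.model4, delta=truth.delta,
            planted=truth.planted, interventions=[],
            missingness=truth.missingness,
            motivation_coef=truth.motivation_coef, pain_coef=truth.pain_coef,
        )
        series, _ = simulate_ema(baseline_truth, sched, seed=rep_seed, registry=registry)
        if use_truth_matrix:
            est_rank = ct.rank_candidates(
                ct.tec(truth.model4, truth.delta, outcome=outcome),
                model=truth.model4, outcome=outcome)
            est_scores = true_scores
        else:
            series = _drop_empty(series)
            try:
                plan = guide_treatment(series, registry, config, seed=rep_seed)
            except Exception:
                rows.append(dict(replicate=rep, mcni_ok=False, lcni_ok=False,
                                 concordance=np.nan, failed=True))
                continue
            est_rank = plan.provenance["stage1_ranking"]
            est_scores = plan.provenance["stage1_tec"].set_index("node")["point"]
        mcni_ok = est_rank[0] == truth.planted["mcni_composite"]
        lcni_ok = est_rank[-1] == truth.planted["lcni_composite"]
        tau, _ = kendalltau(true_scores.loc[list(COMPOSITES)],
                            est_scores.loc[list(COMPOSITES)])
        rows.append(dict(replicate=rep, mcni_ok=mcni_ok, lcni_ok=lcni_ok,
                         concordance=tau, failed=False))
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "mcni_recovery_rate": float(table["mcni_ok"].mean()),
        "lcni_recovery_rate": float(table["lcni_ok"].mean()),
        "mean_concordance": float(table["concordance"].mean()),
        "n_replicates": n_replicates,
        "occasions": occasions,
    }


def _drop_empty(series: EMASeries) -> EMASeries:
    keep = series.data.notna().any(axis=1).to_numpy()
    return EMASeries(
        participant=series.participant,
        data=series.data.loc[keep],
        phase=series.phase.loc[keep],
        observed=series.observed.loc[keep],
    )
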