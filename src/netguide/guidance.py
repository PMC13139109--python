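"""Two-stage centrality-guided treatment-target selection.

Stage 1 fits a CT-VAR network on the three inflexibility composites plus
the interference outcome and ranks the composites by total effect
centrality at delta = the median assessment interval: the maximum becomes
the most-central-node intervention (MCNI) composite, the minimum the
least-central (LCNI).  Stage 2 fits two three-node facet networks — the
two facets of each selected composite plus interference — and orders the
facet sessions: most central facet first in the MCNI phase, least
central facet first in the LCNI phase.  Design randomization draws a
baseline length uniformly from 14-20 days and a fair coin for phase
order.

Each facet maps to two treatment-session content identifiers
(acceptance, defusion, present-moment awareness, self-as-context, values
clarity, committed action).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import centrality as ct
from .ctvar import DriftModel, FitConfig, FitResult, fit_ctvar
from .dtnet import detrend_and_transform, dt_centrality, fit_dtvar, strongest_edge_to_outcome
from .ema import COMPOSITES, EMASeries, ItemRegistry, build_composites, interpolate_missing

__all__ = [
    "INTERVENTION_MAP",
    "PhasePlan",
    "GuidanceConfig",
    "randomize_design",
    "guide_treatment",
    "guide_from_models",
    "alternative_guidance_grid",
]

#: Facet code -> the two session content identifiers delivered for it.
INTERVENTION_MAP: dict[str, tuple[str, str]] = {
    "EA": ("acceptance-1", "acceptance-2"),
    "Fusion": ("defusion-1", "defusion-2"),
    "LPMA": ("present-moment-awareness-1", "present-moment-awareness-2"),
    "SAC": ("self-as-context-1", "self-as-context-2"),
    "LV": ("values-clarity-1", "values-clarity-2"),
    "Inaction": ("committed-action-1", "committed-action-2"),
}

BASELINE_RANGE = (14, 20)  # days, inclusive


def randomize_design(seed: int | None = None) -> tuple[int, str]:
    """Randomize baseline length (uniform 14-20 days) and phase order."""
    rng = np.random.default_rng(seed)
    length = int(rng.integers(BASELINE_RANGE[0], BASELINE_RANGE[1] + 1))
    order = "MCNI-first" if rng.random() < 0.5 else "LCNI-first"
    return length, order


@dataclass
class GuidanceConfig:
    delta: str | float = "median"  # 'median' or hours
    min_occasions: int = 30
    bootstrap: int = 0
    measurement_noise: str = "free"
    stage2: bool = True
    maxiter: int = 400

    def fit_config(self) -> FitConfig:
        return FitConfig(
            min_occasions=self.min_occasions, bootstrap=self.bootstrap,
            measurement_noise=self.measurement_noise, maxiter=self.maxiter,
        )


@dataclass
class PhasePlan:
    participant: str
    baseline_days: int
    order: str  # 'MCNI-first' | 'LCNI-first'
    mcni_composite: str
    mcni_facet_order: tuple[str, str]  # facet codes, most central first
    lcni_composite: str
    lcni_facet_order: tuple[str, str]  # facet codes, least central first
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mcni_composite == self.lcni_composite:
            raise ValueError("MCNI and LCNI composites must differ")

    def sessions(self, phase: str) -> list[str]:
        facets = self.mcni_facet_order if phase == "MCNI" else self.lcni_facet_order
        return [s for f in facets for s in INTERVENTION_MAP[f]]

    def to_dict(self, redact: bool = False) -> dict:
        doc = {
            "participant": self.participant,
            "baseline_days": self.baseline_days,
            "order": self.order,
            "phases": {
                "MCNI": {"sessions": self.sessions("MCNI")},
                "LCNI": {"sessions": self.sessions("LCNI")},
            },
        }
        if not redact:  # blinded export hides which nodes drove the plan
            doc["phases"]["MCNI"].update(
                composite=self.mcni_composite, facet_order=list(self.mcni_facet_order))
            doc["phases"]["LCNI"].update(
                composite=self.lcni_composite, facet_order=list(self.lcni_facet_order))
            doc["provenance"] = {
                k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
                for k, v in self.provenance.items()
            }
        return doc

    def to_json(self, path: str | Path, redact: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(redact), indent=2, default=str))


# ---------------------------------------------------------------------------
# selection from models (shared by the fitted and the oracle paths)


def _rank(model: DriftModel, delta: float, outcome: str) -> list[str]:
    table = ct.tec(model, delta, outcome=outcome)
    return ct.rank_candidates(table, model=model, outcome=outcome)


def guide_from_models(
    participant: str,
    stage1_model: DriftModel,
    delta: float,
    registry: ItemRegistry,
    stage2_models: dict[str, DriftModel] | None = None,
    seed: int | None = None,
    baseline_days: int | None = None,
    provenance: dict | None = None,
) -> PhasePlan:
    """Build a PhasePlan from (true or fitted) drift models directly."""
    outcome = registry.outcome
    ranking = _rank(stage1_model, delta, outcome)
    mcni, lcni = ranking[0], ranking[-1]
    rand_days, order = randomize_design(seed)
    days = baseline_days if baseline_days is not None else rand_days

    def facet_order(comp: str, most_first: bool) -> tuple[str, str]:
        members = registry.composite_members(comp)
        codes = [registry[m].facet for m in members]
        if stage2_models and comp in stage2_models:
            r = _rank(stage2_models[comp], delta, outcome)
            ordered = [registry[m].facet for m in r if m in members]
        else:
            ordered = sorted(codes)
        return tuple(ordered) if most_first else tuple(ordered[::-1])  # type: ignore[return-value]

    prov = dict(provenance or {})
    prov.setdefault("delta_hours", delta)
    prov.setdefault("stage1_ranking", ranking)
    return PhasePlan(
        participant=participant,
        baseline_days=days,
        order=order,
        mcni_composite=mcni,
        mcni_facet_order=facet_order(mcni, most_first=True),
        lcni_composite=lcni,
        lcni_facet_order=facet_order(lcni, most_first=False),
        provenance=prov,
    )


def _fit_stage(df: pd.DataFrame, config: GuidanceConfig, stage: str) -> FitResult:
    try:
        return fit_ctvar(df, config.fit_config())
    except Exception as exc:
        raise RuntimeError(f"guidance {stage} fit failed: {exc}") from exc


def guide_treatment(
    baseline: EMASeries,
    registry: ItemRegistry,
    config: GuidanceConfig | None = None,
    seed: int | None = None,
) -> PhasePlan:
    """The full two-stage guidance procedure on baseline data.

    The plan is a pure function of (baseline data, config, seed): the
    likelihood optimization is deterministic and the seed feeds only the
    design randomization (and bootstrap, if enabled).
    """
    config = config or GuidanceConfig()
    outcome = registry.outcome
    interp = interpolate_missing(baseline)
    composites = build_composites(interp, registry)
    delta = (composites.median_interval() if config.delta == "median"
             else float(config.delta))

    stage1_df = composites.data[list(COMPOSITES) + [outcome]].dropna()
    stage1 = _fit_stage(stage1_df, config, "stage 1 (composites)")
    ranking = _rank(stage1.model, delta, outcome)
    mcni, lcni = ranking[0], ranking[-1]

    stage2_models: dict[str, DriftModel] = {}
    if config.stage2:
        for comp, stage_name in ((mcni, "stage 2a (MCNI facets)"),
                                 (lcni, "stage 2b (LCNI facets)")):
            members = list(registry.composite_members(comp))
            df = interp.data[members + [outcome]].dropna()
            fit = _fit_stage(df, config, stage_name)
            stage2_models[comp] = fit.model
    prov = {
        "stage1_tec": ct.tec(stage1.model, delta, outcome=outcome).to_frame(),
        "stage1_loglik": stage1.loglik,
        "n_occasions": int(len(stage1_df)),
    }
    return guide_from_models(
        baseline.participant, stage1.model, delta, registry,
        stage2_models=stage2_models or None, seed=seed, provenance=prov,
    )


# ---------------------------------------------------------------------------
# retrospective alternative-guidance grid


def _grid_methods(registry: ItemRegistry, composites_df, facets_df, delta, small_delta,
                  config: GuidanceConfig):
    """Yield (method name, callable) pairs; each callable returns a node name."""
    outcome = registry.outcome
    facet_names = [it.name for it in registry.facet_items]

    models: dict[str, DriftModel] = {}

    def model_for(nodes_key: str) -> DriftModel:
        if nodes_key not in models:
            df = composites_df if nodes_key == "4" else facets_df
            models[nodes_key] = fit_ctvar(df, config.fit_config()).model
        return models[nodes_key]

    def ct_pick(nodes_key, kind, d):
        m = model_for(nodes_key)
        fn = ct.tec if kind == "TEC" else ct.iec
        return ct.rank_candidates(fn(m, d, outcome=outcome), model=m, outcome=outcome)[0]

    def ct_path(nodes_key, d):
        m = model_for(nodes_key)
        return strongest_edge_to_outcome((ct.effect_matrix(m, d), m.names), outcome)

    dt_nets: dict[tuple[str, bool], object] = {}

    def dt_net(nodes_key, penalized):
        key = (nodes_key, penalized)
        if key not in dt_nets:
            df = composites_df if nodes_key == "4" else facets_df
            resid = detrend_and_transform(df)
            _, net = fit_dtvar(resid, penalized=penalized)
            dt_nets[key] = net
        return dt_nets[key]

    def dt_pick(nodes_key, penalized, index):
        net = dt_net(nodes_key, penalized)
        table = dt_centrality(net, outcome=outcome).table
        col = table[index]
        if col.abs().max() <= 1e-12:
            return None  # empty network: no meaningful candidate
        return sorted(col.index, key=lambda n: (-col[n], n))[0]

    def dt_path(nodes_key, penalized):
        return strongest_edge_to_outcome(dt_net(nodes_key, penalized), outcome)

    def highest_mean():
        means = facets_df[facet_names].mean()
        return means.idxmax()

    methods = {}
    for key, label in (("4", "4 variables"), ("7", "7 variables")):
        methods[f"CT TEC point estimate ({label})"] = lambda k=key: ct_pick(k, "TEC", delta)
        methods[f"CT IEC point estimate ({label})"] = lambda k=key: ct_pick(k, "IEC", delta)
        methods[f"CT smaller delta TEC ({label})"] = lambda k=key: ct_pick(k, "TEC", small_delta)
        methods[f"CT smaller delta IEC ({label})"] = lambda k=key: ct_pick(k, "IEC", small_delta)
        methods[f"Strongest CT path to outcome ({label})"] = lambda k=key: ct_path(k, delta)
        for pen, pl in ((True, "penalized"), (False, "unpenalized")):
            methods[f"Strongest {pl} DT contemporaneous path ({label})"] = (
                lambda k=key, p=pen: dt_path(k, p))
            for index in ("strength", "expected_influence", "betweenness", "closeness"):
                methods[f"{pl.capitalize()} DT {index} centrality ({label})"] = (
                    lambda k=key, p=pen, i=index: dt_pick(k, p, i))
    methods["Highest baseline facet mean"] = highest_mean
    return methods


def alternative_guidance_grid(
    baseline: EMASeries,
    registry: ItemRegistry,
    config: GuidanceConfig | None = None,
    small_delta: float = 1.0,
) -> pd.DataFrame:
    """Selected node under each retrospective guidance method.

    Columns: method, selected node (NA when that method errored on this
    participant's data — individual failures never abort the grid).
    ``small_delta`` (hours) is the "smaller delta-time" probe.
    """
    config = config or GuidanceConfig()
    outcome = registry.outcome
    interp = interpolate_missing(baseline)
    comps = build_composites(interp, registry)
    delta = (comps.median_interval() if config.delta == "median" else float(config.delta))
    facet_names = [it.name for it in registry.facet_items]
    composites_df = comps.data[list(COMPOSITES) + [outcome]].dropna()
    facets_df = interp.data
    methods = _grid_methods(registry, composites_df,
                            facets_df[facet_names + [outcome]].dropna(),
                            delta, small_delta, config)
    # descriptive correlation methods, one per outcome-like item present
    out_items = [outcome, *registry.role_items("motivation"),
                 *registry.role_items("pain-intensity")]

    def best_corr(out_item):
        sub = facets_df[facet_names + [out_item]].dropna()
        return sub[facet_names].corrwith(sub[out_item]).abs().idxmax()

    for out_item in out_items:
        if out_item in facets_df.columns:
            methods[f"Max |baseline correlation| with {out_item}"] = (
                lambda o=out_item: best_corr(o))
    rows = []
    for name, fn in methods.items():
        try:
            sel = fn()
        except Exception:
            sel = None
        rows.append({"method": name, "selected": sel if sel is not None else pd.NA})
    return pd.DataFrame(rows)
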