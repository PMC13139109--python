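"""EMA data model: item registry, time-stamped series, composites, interpolation.

Ecological momentary assessment (EMA) data arrive as long-format tables —
one row per participant x occasion x item — on a 0-100 visual-analogue
scale.  This module owns validation, round-trip CSV I/O, construction of
the three psychological-inflexibility composites (each the mean of two
facet items), and phase-bounded linear interpolation of missing values.

Timestamps are continuous hours since study start (the response time, not
the prompt time).  Phases are ``baseline -> phase1 -> phase2`` and must be
contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Item",
    "ItemRegistry",
    "EMASeries",
    "CompositeSeries",
    "ValidationError",
    "PHASES",
    "FACETS",
    "COMPOSITES",
    "default_registry",
    "read_ema",
    "write_ema",
    "build_composites",
    "interpolate_missing",
]

PHASES = ("baseline", "phase1", "phase2")

#: Facet code -> composite. Experiential avoidance and fusion form the
#: (lack of) openness composite; lack of present-moment awareness and
#: self-as-content form awareness; lack of values clarity and inaction
#: form engagement.
FACETS: Mapping[str, str] = {
    "EA": "openness",
    "Fusion": "openness",
    "LPMA": "awareness",
    "SAC": "awareness",
    "LV": "engagement",
    "Inaction": "engagement",
}

COMPOSITES = ("openness", "awareness", "engagement")

ROLES = ("outcome-interference", "motivation", "pain-intensity", "facet")
CADENCES = ("five-daily", "once-daily")


class ValidationError(ValueError):
    """Raised when an input table or series violates the data contract."""


@dataclass(frozen=True)
class Item:
    name: str
    role: str
    cadence: str = "five-daily"
    facet: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for item {self.name!r}")
        if self.cadence not in CADENCES:
            raise ValidationError(f"unknown cadence {self.cadence!r} for item {self.name!r}")
        if self.role == "facet":
            if self.facet not in FACETS:
                raise ValidationError(
                    f"facet item {self.name!r} needs a facet code in {sorted(FACETS)}"
                )
        elif self.facet is not None:
            raise ValidationError(f"non-facet item {self.name!r} must not carry a facet code")

    @property
    def composite(self) -> str | None:
        return FACETS[self.facet] if self.facet else None


@dataclass(frozen=True)
class ItemRegistry:
    """The study's daily-assessment item set.

    Invariants: exactly six facet items covering all six facet codes (two
    per composite) and exactly one interference-outcome item.
    """

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate item names in registry")
        facets = [it.facet for it in self.items if it.role == "facet"]
        if sorted(facets) != sorted(FACETS):
            raise ValidationError(
                f"registry must contain exactly the six facets {sorted(FACETS)}, got {sorted(facets)}"
            )
        n_out = sum(it.role == "outcome-interference" for it in self.items)
        if n_out != 1:
            raise ValidationError(f"registry needs exactly one outcome-interference item, got {n_out}")

    # -- lookups ---------------------------------------------------------
    def __iter__(self):
        return iter(self.items)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self.items)

    def __getitem__(self, name: str) -> Item:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    @property
    def outcome(self) -> str:
        return next(it.name for it in self.items if it.role == "outcome-interference")

    @property
    def facet_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.role == "facet")

    def facet_name(self, code: str) -> str:
        return next(it.name for it in self.facet_items if it.facet == code)

    def composite_members(self, composite: str) -> tuple[str, str]:
        """Item names of the two facets forming ``composite``."""
        members = tuple(it.name for it in self.facet_items if it.composite == composite)
        assert len(members) == 2
        return members  # type: ignore[return-value]

    def role_items(self, role: str) -> tuple[str, ...]:
        return tuple(it.name for it in self.items if it.role == role)

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "items": [
                {k: v for k, v in
                 dict(name=it.name, role=it.role, cadence=it.cadence, facet=it.facet).items()
                 if v is not None}
                for it in self.items
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ItemRegistry":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        return cls(tuple(Item(**d) for d in doc["items"]))


def default_registry() -> ItemRegistry:
    """The study's nine daily items: interference, motivation (once daily),
    pain intensity, and the six inflexibility facets."""
    return ItemRegistry(
        (
            Item("interference", "outcome-interference"),
            Item("motivation", "motivation", cadence="once-daily"),
            Item("pain_intensity", "pain-intensity"),
            Item("avoidance", "facet", facet="EA"),
            Item("fusion", "facet", facet="Fusion"),
            Item("lack_of_awareness", "facet", facet="LPMA"),
            Item("self_as_content", "facet", facet="SAC"),
            Item("lack_of_values", "facet", facet="LV"),
            Item("inaction", "facet", facet="Inaction"),
        )
    )


# ---------------------------------------------------------------------------
# series containers


def _validate_panel(data: pd.DataFrame, phase: pd.Series, where: str) -> None:
    t = np.asarray(data.index, dtype=float)
    if len(t) and not np.all(np.diff(t) > 0):
        bad = int(np.argmin(np.diff(t) > 0))
        raise ValidationError(f"{where}: timestamps not strictly increasing near row {bad + 1}")
    unknown = set(phase.unique()) - set(PHASES)
    if unknown:
        raise ValidationError(f"{where}: unknown phase labels {sorted(unknown)}")
    # phases contiguous and ordered
    codes = phase.map({p: i for i, p in enumerate(PHASES)}).to_numpy()
    if len(codes) and np.any(np.diff(codes) < 0):
        raise ValidationError(f"{where}: phases out of order (must be baseline->phase1->phase2)")
    vals = data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 100)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValidationError(
            f"{where}: value {vals[i, j]:g} for item {data.columns[j]!r} at "
            f"t={data.index[i]:g} outside [0, 100]"
        )


@dataclass
class EMASeries:
    """One participant's multivariate EMA record.

    ``data`` is wide: rows indexed by timestamp (hours since study start),
    one column per item, ``NaN`` marking a missing response.  ``phase``
    aligns with the rows.  ``observed`` remembers original missingness
    through transformations such as interpolation.
    """

    participant: str
    data: pd.DataFrame
    phase: pd.Series
    observed: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = self.data.sort_index()
        self.phase = self.phase.reindex(self.data.index)
        if self.observed is None:
            self.observed = self.data.notna()
        else:
            self.observed = self.observed.reindex_like(self.data).fillna(False)
        _validate_panel(self.data, self.phase, f"participant {self.participant!r}")

    # -- convenience -----------------------------------------------------
    @property
    def timestamps(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def n_occasions(self) -> int:
        return len(self.data)

    def phase_slice(self, phase: str) -> pd.DataFrame:
        return self.data.loc[(self.phase == phase).to_numpy()]

    def subset(self, items: Iterable[str]) -> "EMASeries":
        items = list(items)
        return replace(
            self,
            data=self.data[items].copy(),
            phase=self.phase.copy(),
            observed=self.observed[items].copy(),
        )

    def median_interval(self) -> float:
        """Median gap between consecutive occasions, in hours."""
        t = self.timestamps
        if len(t) < 2:
            raise ValidationError("need at least two occasions for an interval")
        return float(np.median(np.diff(t)))


@dataclass
class CompositeSeries(EMASeries):
    """EMASeries whose facet items were replaced by the three composites.

    ``single_member`` flags occasions where a composite was computed from
    only one observed facet.
    """

    single_member: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.single_member is None:
            self.single_member = pd.DataFrame(
                False, index=self.data.index,
                columns=[c for c in COMPOSITES if c in self.data.columns],
            )


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ["participant", "timestamp", "phase", "item", "value"]


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Accept numeric hours or ISO-8601; ISO converts to hours since the
    midnight preceding the earliest timestamp."""
    num = pd.to_numeric(raw, errors="coerce")
    if num.notna().all():
        return num.astype(float)
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if ts.isna().any():
        bad = raw[ts.isna() & num.isna()].index[0]
        raise ValidationError(f"row {bad}: unparseable timestamp {raw[bad]!r}")
    origin = ts.min().normalize()
    return (ts - origin).dt.total_seconds() / 3600.0


def read_ema(path: str | Path, registry: ItemRegistry) -> EMASeries:
    """Read one participant's long-format CSV into a validated EMASeries.

    Columns: participant, timestamp, phase, item, value (empty = missing).
    Unknown items, out-of-range values and non-monotone timestamps are
    rejected with the offending row named.
    """
    df = pd.read_csv(path, dtype={"participant": str, "phase": str, "item": str})
    missing_cols = set(_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    participants = df["participant"].unique()
    if len(participants) != 1:
        raise ValidationError(f"{path}: expected one participant, found {list(participants)}")
    unknown = set(df["item"].unique()) - set(registry.names)
    if unknown:
        row = df.index[df["item"].isin(unknown)][0]
        raise ValidationError(f"{path} row {row}: unknown item(s) {sorted(unknown)}")
    df = df.assign(hours=_parse_timestamps(df["timestamp"]))
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.notna() & ((vals < 0) | (vals > 100))
    if bad.any():
        row = df.index[bad][0]
        raise ValidationError(f"{path} row {row}: value {vals[row]:g} outside [0, 100]")
    try:
        wide = df.pivot(index="hours", columns="item", values="value")
    except ValueError as exc:
        raise ValidationError(f"{path}: duplicate (timestamp, item) rows: {exc}") from exc
    wide = wide.astype(float)
    # preserve registry column order for items present
    wide = wide[[n for n in registry.names if n in wide.columns]]
    wide.index.name = None
    wide.columns.name = None
    phase = df.drop_duplicates("hours").set_index("hours")["phase"].reindex(wide.index)
    return EMASeries(participant=str(participants[0]), data=wide, phase=phase)


def write_ema(series: EMASeries, path: str | Path) -> None:
    """Write a series back to long-format CSV (inverse of :func:`read_ema`)."""
    rows = series.data.reset_index(names="timestamp").melt(
        id_vars="timestamp", var_name="item", value_name="value"
    )
    rows["phase"] = series.phase.reindex(rows["timestamp"]).to_numpy()
    rows["participant"] = series.participant
    rows = rows.sort_values(["timestamp", "item"], kind="stable")
    rows[_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# composites


def build_composites(series: EMASeries, registry: ItemRegistry) -> CompositeSeries:
    """Replace the six facet items by their three per-occasion composites.

    Each composite is the arithmetic mean of its two member facets (keeps
    the 0-100 scale).  If one member is missing at an occasion the
    observed member is used alone and the occasion is flagged; if both are
    missing the composite is missing.  Non-facet items pass through.
    """
    passthrough = [it.name for it in registry if it.role != "facet" and it.name in series.items]
    out = {}
    flags = {}
    for comp in COMPOSITES:
        m1, m2 = registry.composite_members(comp)
        pair = series.data[[m1, m2]]
        out[comp] = pair.mean(axis=1, skipna=True)
        flags[comp] = pair.isna().sum(axis=1) == 1
    data = pd.concat({**{c: out[c] for c in COMPOSITES},
                      **{n: series.data[n] for n in passthrough}}, axis=1)
    data = data[list(COMPOSITES) + passthrough]
    return CompositeSeries(
        participant=series.participant,
        data=data,
        phase=series.phase.copy(),
        observed=data.notna(),
        single_member=pd.DataFrame(flags),
    )


# ---------------------------------------------------------------------------
# interpolation


def interpolate_missing(series: EMASeries) -> EMASeries:
    """Fill missing values by linear-in-time interpolation within phase.

    Interior gaps interpolate linearly in clock time between the nearest
    observed neighbours of the same phase; leading/trailing gaps within a
    phase carry the nearest observed value.  Values are never interpolated
    across a phase boundary.  The original missingness mask is retained in
    ``observed``.  An item entirely missing within a phase is an error.
    """
    data = series.data.copy()
    t = series.timestamps
    for phase in PHASES:
        mask = (series.phase == phase).to_numpy()
        if not mask.any():
            continue
        tp = t[mask]
        block = data.loc[mask]
        for col in data.columns:
            y = block[col].to_numpy(dtype=float)
            obs = ~np.isnan(y)
            if obs.all():
                continue
            if not obs.any():
                raise ValidationError(
                    f"item {col!r} entirely missing in phase {phase!r}; cannot interpolate"
                )
            # np.interp carries endpoints, giving the nearest-value rule
            data.loc[mask, col] = np.interp(tp, tp[obs], y[obs])
    return replace(
        series, data=data, phase=series.phase.copy(), observed=series.observed.copy()
    )
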