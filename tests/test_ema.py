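import numpy as np
import pandas as pd
import pytest

from netguide.ema import (
    ItemRegistry,
    Item,
    ValidationError,
    build_composites,
    interpolate_missing,
    read_ema,
    write_ema,
)


class TestRegistry:
    def test_default_structure(self, registry):
        assert len(registry.facet_items) == 6
        assert registry.outcome == "interference"
        for comp in ("openness", "awareness", "engagement"):
            assert len(registry.composite_members(comp)) == 2

    def test_rejects_incomplete_facet_set(self):
        items = [Item("interference", "outcome-interference"),
                 Item("avoidance", "facet", facet="EA")]
        with pytest.raises(ValidationError, match="six facets"):
            ItemRegistry(tuple(items))

    def test_yaml_round_trip(self, registry, tmp_path):
        path = tmp_path / "items.yaml"
        registry.to_yaml(path)
        assert ItemRegistry.from_yaml(path) == registry


class TestIO:
    def _write_long(self, tmp_path, rows):
        path = tmp_path / "ema.csv"
        pd.DataFrame(rows, columns=["participant", "timestamp", "phase", "item", "value"]
                     ).to_csv(path, index=False)
        return path

    def test_out_of_range_value_rejected(self, registry, tmp_path):
        rows = [("p1", 8.0, "baseline", "interference", 50),
                ("p1", 11.0, "baseline", "interference", 101),
                ("p1", 14.0, "baseline", "interference", 40)]
        with pytest.raises(ValidationError, match="101"):
            read_ema(self._write_long(tmp_path, rows), registry)

    def test_unknown_item_rejected(self, registry, tmp_path):
        rows = [("p1", 8.0, "baseline", "mystery", 50)]
        with pytest.raises(ValidationError, match="mystery"):
            read_ema(self._write_long(tmp_path, rows), registry)

    def test_round_trip(self, registry, tmp_path, series_builder):
        s = series_builder(
            {"interference": [50, np.nan, 30], "avoidance": [10, 20, 30]},
            times=[8.0, 11.5, 14.2],
            phases=["baseline", "baseline", "phase1"],
        )
        path = tmp_path / "out.csv"
        write_ema(s, path)
        back = read_ema(path, registry)
        pd.testing.assert_frame_equal(back.data, s.data[back.data.columns])
        assert list(back.phase) == list(s.phase)

    def test_iso_timestamps_accepted(self, registry, tmp_path):
        rows = [("p1", "2024-03-01T08:15:00", "baseline", "interference", 50),
                ("p1", "2024-03-01T11:30:00", "baseline", "interference", 60)]
        s = read_ema(self._write_long(tmp_path, rows), registry)
        assert s.timestamps == pytest.approx([8.25, 11.5])

    def test_generator_output_parses(self, registry, tmp_path, truth):
        from netguide.synth import make_schedule, simulate_ema

        sched = make_schedule(14, 3, 3, seed=5)
        series, _ = simulate_ema(truth, sched, seed=5, registry=registry)
        path = tmp_path / "sim.csv"
        write_ema(series, path)
        back = read_ema(path, registry)
        assert back.n_occasions() == sched.n_occasions()


class TestComposites:
    def test_mean_of_members(self, registry, series_builder):
        s = series_builder({"avoidance": [10.0], "fusion": [30.0],
                            "lack_of_awareness": [0.0], "self_as_content": [0.0],
                            "lack_of_values": [0.0], "inaction": [0.0],
                            "interference": [55.0]})
        comp = build_composites(s, registry)
        assert comp.data["openness"].iloc[0] == 20.0
        assert comp.data["interference"].iloc[0] == 55.0

    def test_single_member_fallback_flagged(self, registry, series_builder):
        s = series_builder({"avoidance": [10.0], "fusion": [np.nan],
                            "lack_of_awareness": [5.0], "self_as_content": [7.0],
                            "lack_of_values": [1.0], "inaction": [3.0],
                            "interference": [55.0]})
        comp = build_composites(s, registry)
        assert comp.data["openness"].iloc[0] == 10.0
        assert comp.single_member["openness"].iloc[0]
        assert not comp.single_member["awareness"].iloc[0]

    def test_facet_level_means_aggregate(self, registry, series_builder):
        # openness composite of series with facet means 14.2 and 48.2 -> 31.2
        rng = np.random.default_rng(0)
        ea = 14.2 + rng.normal(0, 1, 50)
        fu = 48.2 + rng.normal(0, 1, 50)
        ea += 14.2 - ea.mean()
        fu += 48.2 - fu.mean()
        s = series_builder({"avoidance": ea, "fusion": fu,
                            "lack_of_awareness": np.full(50, 19.3),
                            "self_as_content": np.full(50, 47.9),
                            "lack_of_values": np.full(50, 40.6),
                            "inaction": np.full(50, 49.4),
                            "interference": np.full(50, 50.0)})
        comp = build_composites(s, registry)
        assert comp.data["openness"].mean() == pytest.approx(31.2, abs=1e-9)

    def test_commutes_with_subsetting(self, registry, series_builder):
        rng = np.random.default_rng(1)
        cols = {it.name: rng.uniform(0, 100, 12) for it in registry}
        s = series_builder(cols)
        full = build_composites(s, registry).data.iloc[3:9]
        sub = s.data.iloc[3:9]
        from netguide.ema import EMASeries
        s2 = EMASeries("p1", sub, s.phase.iloc[3:9])
        part = build_composites(s2, registry).data
        pd.testing.assert_frame_equal(full, part)


class TestInterpolation:
    def _mini(self, series_builder, vals, times=None, phases=None):
        base = {"avoidance": vals, "fusion": vals, "lack_of_awareness": vals,
                "self_as_content": vals, "lack_of_values": vals,
                "inaction": vals, "interference": vals}
        return series_builder(base, times=times, phases=phases)

    def test_linear_midpoint(self, series_builder):
        s = self._mini(series_builder, [10.0, np.nan, 20.0])
        out = interpolate_missing(s)
        assert out.data["interference"].iloc[1] == 15.0
        # original missingness retained
        assert not out.observed["interference"].iloc[1]

    def test_two_consecutive_gaps(self, series_builder):
        s = self._mini(series_builder, [0.0, np.nan, np.nan, 30.0],
                       times=[0.0, 1.0, 2.0, 3.0])
        out = interpolate_missing(s)
        assert list(out.data["interference"]) == [0.0, 10.0, 20.0, 30.0]

    def test_phase_boundary_carries_not_crosses(self, series_builder):
        s = self._mini(series_builder, [10.0, np.nan, 50.0, 60.0],
                       phases=["baseline", "baseline", "phase1", "phase1"])
        out = interpolate_missing(s)
        assert out.data["interference"].iloc[1] == 10.0  # carried, not interpolated to 50

    def test_entirely_missing_phase_errors(self, series_builder):
        s = self._mini(series_builder, [np.nan, np.nan, 50.0, 60.0],
                       phases=["baseline", "baseline", "phase1", "phase1"])
        with pytest.raises(ValidationError, match="baseline"):
            interpolate_missing(s)

    def test_idempotent_and_identity(self, series_builder):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 100, 20)
        vals[[3, 7, 8, 19]] = np.nan
        s = self._mini(series_builder, vals, times=np.sort(rng.uniform(0, 100, 20)))
        once = interpolate_missing(s)
        twice = interpolate_missing(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        # no-missing input is untouched
        clean = self._mini(series_builder, rng.uniform(0, 100, 10))
        pd.testing.assert_frame_equal(interpolate_missing(clean).data, clean.data)


class TestSeriesValidation:
    def test_nonmonotone_timestamps_rejected(self, series_builder):
        with pytest.raises(ValidationError, match="increasing"):
            series_builder({"interference": [1.0, 2.0]}, times=[5.0, 5.0])

    def test_phase_order_enforced(self, series_builder):
        with pytest.raises(ValidationError, match="order"):
            series_builder({"interference": [1.0, 2.0]},
                           phases=["phase1", "baseline"])
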