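import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netguide.sced import (
    VARIANTS,
    bpi_change,
    effect_band,
    evaluate_sced,
    tau_u,
    visual_metrics,
)


def bruteforce_tau_u(a, b, variant):
    """Independent oracle: direct enumeration of every pair."""
    a, b = list(a), list(b)
    na, nb = len(a), len(b)
    sgn = lambda d: int(d > 0) - int(d < 0)
    S_AB = sum(sgn(bj - ai) for ai in a for bj in b)
    S_tA = sum(sgn(a[j] - a[i]) for i in range(na) for j in range(i + 1, na))
    S_tB = sum(sgn(b[j] - b[i]) for i in range(nb) for j in range(i + 1, nb))
    S = S_AB
    denom = na * nb
    if "TrendB" in variant:
        S += S_tB
        denom += nb * (nb - 1) // 2
    if "TrendA" in variant:
        S -= S_tA
        denom += na * (na - 1) // 2
    return S, denom


class TestTauU:
    def test_complete_separation(self):
        r = tau_u([1, 2, 3], [4, 5, 6], "AvsB")
        assert r.S_AB == 9
        assert r.tau == 1.0

    def test_full_variant_worked_example(self):
        r = tau_u([1, 2, 3], [4, 5, 6], "AvsB+TrendB-TrendA")
        assert (r.S_AB, r.S_trendB, r.S_trendA) == (9, 3, 3)
        assert r.S_total == 9
        assert r.denominator == 15
        assert r.tau == pytest.approx(0.6)

    def test_all_ties_zero(self):
        for variant in VARIANTS:
            r = tau_u([5, 5, 5, 5], [5, 5, 5], variant)
            assert r.tau == 0.0
            assert r.z == 0.0

    def test_too_short_phase_errors(self):
        with pytest.raises(ValueError, match="too short"):
            tau_u([1, 2], [3, 4, 5])

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_bruteforce_oracle(self, variant):
        rng = np.random.default_rng(40)
        for _ in range(80):
            na, nb = rng.integers(3, 13, size=2)
            # mix continuous values and heavy ties
            if rng.random() < 0.5:
                a, b = rng.normal(size=na), rng.normal(size=nb)
            else:
                a, b = rng.integers(0, 4, na), rng.integers(0, 4, nb)
            r = tau_u(a, b, variant)
            S, denom = bruteforce_tau_u(a, b, variant)
            assert r.S_total == S
            assert r.denominator == denom
            assert r.tau == pytest.approx(S / denom)

    def test_antisymmetry_of_ab_variant(self):
        rng = np.random.default_rng(41)
        a, b = rng.normal(size=8), rng.normal(size=10)
        assert tau_u(a, b, "AvsB").tau == pytest.approx(-tau_u(b, a, "AvsB").tau)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=10),
           st.lists(st.floats(-50, 50), min_size=4, max_size=10))
    def test_rank_invariance(self, a, b):
        """Tau-U is a rank statistic: any strictly increasing transform of
        all values jointly leaves it unchanged."""
        a = [round(v, 3) for v in a]  # keep the transform numerically strict
        b = [round(v, 3) for v in b]
        r1 = tau_u(a, b)
        f = lambda x: np.exp(np.asarray(x) / 25.0) * 3 + 1
        r2 = tau_u(f(a), f(b))
        assert r1.S_total == r2.S_total
        assert r1.tau == r2.tau

    def test_sd_matches_permutation_sd(self):
        """Additive SD_S vs the permutation distribution of S under the
        exchangeable null."""
        rng = np.random.default_rng(42)
        na = nb = 30
        pool = rng.normal(size=na + nb)
        stats = []
        for _ in range(4000):
            perm = rng.permutation(pool)
            r = tau_u(perm[:na], perm[na:])
            stats.append(r.S_total)
        analytic = tau_u(pool[:na], pool[na:]).SD_S
        assert np.std(stats) == pytest.approx(analytic, rel=0.03)


class TestEffectBands:
    @pytest.mark.parametrize("tau,band", [
        (0.1, "small"), (-0.19, "small"), (0.2, "moderately high"),
        (0.59, "moderately high"), (0.7, "high"), (-0.75, "high"),
        (0.81, "very high"), (-0.95, "very high"),
    ])
    def test_bands(self, tau, band):
        assert effect_band(tau) == band


def three_phase_series(series_builder, values, item="interference", n_per=10):
    phases = ["baseline"] * n_per + ["phase1"] * n_per + ["phase2"] * n_per
    cols = {item: values}
    return series_builder(cols, phases=phases)


class TestEvaluateSced:
    def test_contrast_table_shape(self, series_builder):
        rng = np.random.default_rng(43)
        s = three_phase_series(series_builder, rng.uniform(20, 80, 30))
        out = evaluate_sced(s, ["interference"])
        assert set(out["contrast"]) == {"baseline-phase1", "baseline-phase2",
                                        "phase1-phase2"}
        assert len(out) == 3

    def test_handlings_agree_without_missing(self, series_builder):
        rng = np.random.default_rng(44)
        s = three_phase_series(series_builder, rng.uniform(20, 80, 30))
        t1 = evaluate_sced(s, ["interference"], handling="interpolate")
        t2 = evaluate_sced(s, ["interference"], handling="exclude")
        pd.testing.assert_frame_equal(t1.drop(columns="handling"),
                                      t2.drop(columns="handling"))

    def test_interpolate_vs_exclude_differ_with_missing(self, series_builder):
        rng = np.random.default_rng(45)
        vals = rng.uniform(20, 80, 30)
        vals[[2, 5, 12, 22]] = np.nan
        s = three_phase_series(series_builder, vals)
        t1 = evaluate_sced(s, ["interference"], handling="interpolate")
        t2 = evaluate_sced(s, ["interference"], handling="exclude")
        assert (t1["nA"] + t1["nB"]).sum() > (t2["nA"] + t2["nB"]).sum()

    def test_missing_phase_errors(self, series_builder):
        s = series_builder({"interference": np.arange(10.0)},
                           phases=["baseline"] * 5 + ["phase1"] * 5)
        with pytest.raises(ValueError, match="phase2"):
            evaluate_sced(s, ["interference"])

    def test_planted_drop_detected(self, series_builder):
        """A large phase-onset drop that ramps in (as interventions do)
        yields a strongly negative trend-corrected Tau-U.  Note the full
        variant's denominator caps |tau| at nA*nB/denom ~ 0.52 for a pure
        level shift; the ramp's within-phase trend is what pushes the
        statistic into the high band."""
        rng = np.random.default_rng(46)
        base = rng.normal(60, 3, 15)
        drop = np.r_[np.linspace(55, 25, 7), rng.normal(25, 3, 8)]
        back = rng.normal(25, 3, 15)
        s = three_phase_series(series_builder, np.r_[base, drop, back], n_per=15)
        out = evaluate_sced(s, ["interference"])
        row = out[out["contrast"] == "baseline-phase1"].iloc[0]
        assert row["tau"] < -0.6
        assert row["band"] in ("high", "very high")
        assert row["p"] < 0.01


class TestVisualMetrics:
    def test_no_overlap(self, series_builder):
        s = three_phase_series(series_builder,
                               np.r_[np.arange(10, 20), np.arange(50, 60),
                                     np.arange(50, 60)].astype(float))
        vm = visual_metrics(s, "interference")
        c = vm.contrasts[0]
        assert c.overlap_percent == 0.0
        assert not c.high_overlap

    def test_identical_phases_full_overlap(self, series_builder):
        vals = np.r_[np.arange(10.0), np.arange(10.0), np.arange(10.0)]
        s = three_phase_series(series_builder, vals)
        vm = visual_metrics(s, "interference")
        c = vm.contrasts[0]
        assert c.overlap_percent == 100.0
        assert c.immediacy == pytest.approx(abs(np.arange(10.0)[-5:].mean()
                                                - np.arange(10.0)[:5].mean()))

    def test_hand_counted_overlap(self, series_builder):
        vals = np.r_[[10, 20, 30, 40, 50], [35, 45, 55, 60], [50, 50, 50, 50, 50, 50]]
        phases = ["baseline"] * 5 + ["phase1"] * 4 + ["phase2"] * 6
        s = series_builder({"interference": np.asarray(vals, float)}, phases=phases)
        vm = visual_metrics(s, "interference")
        c = vm.contrasts[0]
        assert c.overlap_percent == pytest.approx(50.0)  # 35, 45 inside [10, 50]
        assert c.immediacy is None  # phase1 has only 4 points

    def test_phase_stats(self, series_builder):
        vals = np.r_[np.linspace(0, 9, 10), np.full(10, 5.0), np.full(10, 7.0)]
        s = three_phase_series(series_builder, vals)
        vm = visual_metrics(s, "interference")
        assert vm.phase_stats.loc["baseline", "slope"] == pytest.approx(1.0)
        assert vm.phase_stats.loc["phase1", "mean"] == 5.0


class TestBPI:
    def test_worked_improvement(self):
        # pre 6.29 -> post 4.14: change 2.15, meaningful improvement
        r = bpi_change(6.29, 4.14)
        assert r["change"] == pytest.approx(2.15)
        assert r["improved"] and not r["worsened"]

    def test_threshold_inclusive(self):
        assert bpi_change(5.0, 4.13)["improved"]
        assert not bpi_change(5.0, 4.14)["improved"]

    def test_worsening(self):
        r = bpi_change(4.00, 6.29)
        assert r["worsened"] and not r["improved"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bpi_change(11.0, 5.0)
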