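"""Two-way ANOVA effect decomposition, inclusion rule and stage tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexlink import (
    STAGE_GH,
    STAGE_T,
    SpikeTrain,
    TrialRecord,
    WindowGrid,
    anova2_eta,
    corrected_threshold,
    effect_series,
    include_unit,
    stage_compare,
)
from cortexlink.tuning import FACTORS, EffectSeries, stage_windows


def brute_force_ss(y, a_labels, b_labels):
    """Independent oracle: direct Type-II sum-of-squares decomposition via
    model comparisons with explicit design matrices."""
    y = np.asarray(y, dtype=float)
    a_levels = sorted(set(a_labels))
    b_levels = sorted(set(b_labels))

    def design(cols):
        X = [np.ones_like(y)]
        if "a" in cols:
            X += [(np.asarray(a_labels) == lv).astype(float) for lv in a_levels[1:]]
        if "b" in cols:
            X += [(np.asarray(b_labels) == lv).astype(float) for lv in b_levels[1:]]
        if "ab" in cols:
            for la in a_levels[1:]:
                for lb in b_levels[1:]:
                    X.append(((np.asarray(a_labels) == la)
                              & (np.asarray(b_labels) == lb)).astype(float))
        return np.column_stack(X)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ss_a = rss(design({"b"})) - rss(design({"a", "b"}))
    ss_b = rss(design({"a"})) - rss(design({"a", "b"}))
    ss_ab = rss(design({"a", "b"})) - rss(design({"a", "b", "ab"}))
    ss_e = rss(design({"a", "b", "ab"}))
    denom = ss_a + ss_b + ss_ab + ss_e
    return ss_a / denom, ss_b / denom, ss_ab / denom


class TestAnovaEta:
    def test_pure_texture_effect_is_one(self):
        y = [0, 0, 2, 2, 0, 0, 2, 2]
        tex = ["a", "a", "b", "b", "a", "a", "b", "b"]
        load = [1, 2, 1, 2, 1, 2, 1, 2]
        res = anova2_eta(y, tex, load)
        assert res.eta["texture"] == pytest.approx(1.0)
        assert res.eta["load"] == pytest.approx(0.0, abs=1e-12)
        assert res.eta["interaction"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_is_degenerate(self):
        res = anova2_eta([3.0] * 8, ["a", "a", "b", "b"] * 2, [1, 2, 1, 2] * 2)
        assert res.degenerate
        assert all(res.eta[f] == 0.0 for f in FACTORS)

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError, match="empty design cell"):
            anova2_eta([1, 2, 3, 4], ["a", "a", "b", "b"], [1, 1, 1, 2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        tex = np.repeat(["a", "b", "c"], 15)
        load = np.tile(np.repeat([1, 2, 3], 5), 3)
        y = rng.normal(size=45) + (tex == "b") * rng.normal()
        res = anova2_eta(y, tex, load)
        ea, eb, eab = brute_force_ss(y, tex, load)
        assert res.eta["texture"] == pytest.approx(ea, abs=1e-10)
        assert res.eta["load"] == pytest.approx(eb, abs=1e-10)
        assert res.eta["interaction"] == pytest.approx(eab, abs=1e-10)

    def test_unbalanced_matches_statsmodels_type2(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(7)
        # unbalanced cells (25-30 trials as in the real design)
        rows = []
        for ta in ["a", "b", "c"]:
            for lb in ["x", "y", "z"]:
                for _ in range(int(rng.integers(25, 31))):
                    rows.append((ta, lb, rng.normal() + (ta == "a") * 0.5))
        df = pd.DataFrame(rows, columns=["tex", "load", "y"])
        res = anova2_eta(df["y"], df["tex"], df["load"])
        fit = ols("y ~ C(tex) * C(load)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        ss = {
            "texture": table.loc["C(tex)", "sum_sq"],
            "load": table.loc["C(load)", "sum_sq"],
            "interaction": table.loc["C(tex):C(load)", "sum_sq"],
            "err": table.loc["Residual", "sum_sq"],
        }
        denom = sum(ss.values())
        for f in FACTORS:
            assert res.eta[f] == pytest.approx(ss[f] / denom, rel=1e-8)
            assert res.p[f] == pytest.approx(
                table.loc[{"texture": "C(tex)", "load": "C(load)",
                           "interaction": "C(tex):C(load)"}[f], "PR(>F)"],
                rel=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_scale_and_permutation_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        tex = np.repeat(["a", "b"], 8)
        load = np.tile(np.repeat([1, 2], 4), 2)
        y = rng.normal(size=16)
        base = anova2_eta(y, tex, load)
        scaled = anova2_eta(y * scale, tex, load)
        perm = rng.permutation(16)
        permuted = anova2_eta(y[perm], tex[perm], load[perm])
        for f in FACTORS:
            assert scaled.eta[f] == pytest.approx(base.eta[f], abs=1e-9)
            assert permuted.eta[f] == pytest.approx(base.eta[f], abs=1e-9)

    def test_eta_components_sum_below_one(self):
        rng = np.random.default_rng(3)
        tex = np.repeat(["a", "b", "c"], 10)
        load = np.tile(np.repeat([1, 2], 5), 3)
        res = anova2_eta(rng.normal(size=30), tex, load)
        total = sum(res.eta[f] for f in FACTORS)
        assert 0.0 <= total <= 1.0


class TestCorrectedThreshold:
    def test_default_grid_value(self):
        assert corrected_threshold(0.05, 3, 23, 5) == 0.0036

    def test_identity(self):
        assert corrected_threshold(0.05, 1, 1, 1) == 0.05

    def test_arithmetic(self):
        assert corrected_threshold(0.05, 2, 10, 5) == 0.0125

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            corrected_threshold(0.05, 0, 23, 5)


def _series(p_tex, p_load, eta_tex=None, grid=None):
    grid = grid or WindowGrid.tuning_default()
    n = grid.n_windows
    eta = {f: np.zeros(n) for f in FACTORS}
    if eta_tex is not None:
        eta["texture"] = np.asarray(eta_tex, dtype=float)
    p = {"texture": np.asarray(p_tex, dtype=float),
         "load": np.asarray(p_load, dtype=float),
         "interaction": np.ones(n)}
    return EffectSeries(unit_id="u", grid=grid, eta=eta, p=p,
                        degenerate=np.zeros(n, dtype=bool))


class TestInclusionRule:
    def test_five_texture_windows_suffice(self):
        p_tex = np.ones(23)
        p_tex[:5] = 1e-5
        s = _series(p_tex, np.ones(23))
        assert include_unit(s, threshold=0.0036, min_windows=5).included

    def test_four_and_four_excluded(self):
        p_tex = np.ones(23)
        p_tex[:4] = 1e-5
        p_load = np.ones(23)
        p_load[:4] = 1e-5
        s = _series(p_tex, p_load)
        summary = include_unit(s, threshold=0.0036, min_windows=5)
        assert not summary.included
        assert summary.n_sig == {"texture": 4, "load": 4, "interaction": 0}

    def test_peak_latency_ties_break_early(self):
        eta = np.zeros(23)
        eta[[4, 9]] = 0.5   # tie: windows starting at 0 and 250 ms
        s = _series(np.ones(23), np.ones(23), eta_tex=eta)
        summary = include_unit(s, threshold=0.0036)
        assert summary.peak_latency["texture"] == 0.0

    def test_zero_spike_unit_degenerate_everywhere(self):
        unit = SpikeTrain("z", 0, "M1", times=np.array([]))
        trials = [TrialRecord(i, 0, t, l, 5.0 * i + 1, 5.0 * i + 2, 5.0 * i + 4)
                  for i, (t, l) in enumerate(
                      [(t, l) for t in "ab" for l in (1.0, 2.0)] * 3)]
        series = effect_series(unit, trials)
        assert series.degenerate.all()
        summary = include_unit(series, threshold=0.0036)
        assert not summary.included


class TestStages:
    def test_default_stage_windows(self):
        grid = WindowGrid.tuning_default()
        assert list(grid.starts[stage_windows(grid, STAGE_T)]) == [-50.0]
        assert list(grid.starts[stage_windows(grid, STAGE_GH)]) == [350.0]

    def test_identical_stages_give_p_one(self):
        rng = np.random.default_rng(0)
        series = []
        for _ in range(10):
            eta = rng.random(23)
            s = _series(np.ones(23), np.ones(23), eta_tex=eta)
            series.append(s)
        rep = stage_compare(series, STAGE_T, STAGE_T, "texture")
        assert rep.p == 1.0
        assert rep.direction == 0

    def test_direction_mirrors_when_stages_swap(self):
        rng = np.random.default_rng(1)
        series = [_series(np.ones(23), np.ones(23), eta_tex=rng.random(23) + 0.3)
                  for _ in range(12)]
        fwd = stage_compare(series, STAGE_T, STAGE_GH, "texture")
        rev = stage_compare(series, STAGE_GH, STAGE_T, "texture")
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.direction == -rev.direction

    def test_too_few_units_raises(self):
        with pytest.raises(ValueError):
            stage_compare([_series(np.ones(23), np.ones(23))],
                          STAGE_T, STAGE_GH, "texture")


class TestNullCalibration:
    def test_null_p_fraction_near_alpha(self):
        """Untuned Poisson units: ~5% of windows significant at alpha=0.05."""
        rng = np.random.default_rng(11)
        grid = WindowGrid.regular(-200.0, 800.0, 200.0, 200.0)  # 6 windows
        conditions = [(t, l) for t in "abc" for l in (1.0, 2.0, 3.0)]
        n_units, rate = 120, 15.0
        hits = total = 0
        trials = []
        for i, (t, l) in enumerate(conditions * 6):   # 54 trials
            t0 = 6.0 * i + 2.0
            trials.append(TrialRecord(i, 0, t, l, t0 - 1.0, t0, t0 + 2.0))
        for _ in range(n_units):
            times = []
            for tr in trials:
                n = rng.poisson(rate * 1.4)
                times.append(tr.t_touch - 0.3 + rng.uniform(0, 1.4, n))
            unit = SpikeTrain("u", 0, "M1", np.sort(np.concatenate(times)))
            series = effect_series(unit, trials, grid)
            for f in ("texture", "load"):
                hits += int(np.sum(series.p[f] < 0.05))
                total += grid.n_windows
        frac = hits / total
        sd = np.sqrt(0.05 * 0.95 / total)
        assert frac == pytest.approx(0.05, abs=3.5 * sd)
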