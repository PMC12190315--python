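import math

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_ks
from lickstruct.errors import ValidationError
from lickstruct.stats import (
    MixedModelSpec,
    benjamini_hochberg,
    fit_mixed_model,
    kde,
    ks_two_sample,
    location_test,
    mixed_anova,
)


class TestKS:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_separated_supports(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).statistic == 1.0

    def test_interleaved_example(self):
        assert ks_two_sample([1, 2], [1.5]).statistic == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            n1 = int(rng.integers(1, 31))
            n2 = int(rng.integers(1, 31))
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n2)
            res = ks_two_sample(a, b)
            assert res.statistic == pytest.approx(
                brute_force_ks(a, b), abs=1e-12
            )


class TestKDE:
    def test_normal_sample_peaks_near_zero(self):
        # the empirical mode of one draw wobbles with the bandwidth, so the
        # Monte-Carlo check is on the across-draw mean of the mode location
        modes = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0, 1, 10000)
            grid, dens = kde(x)
            modes.append(grid[np.argmax(dens)])
        assert abs(np.mean(modes)) < 0.05
        assert np.max(np.abs(modes)) < 0.3

    def test_integrates_to_one(self):
        rng = np.random.default_rng(2)
        for sample in (
            rng.normal(5, 2, 50),
            rng.exponential(1, 200),
            np.array([0.0, 1.0]),
        ):
            grid, dens = kde(sample)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValidationError):
            kde([3.0, 3.0, 3.0])

    def test_fixed_bandwidth(self):
        x = np.random.default_rng(1).normal(0, 1, 500)
        grid, dens = kde(x, bandwidth_rule="fixed", bandwidth=0.5)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


class TestLocationTest:
    def test_identical_samples_rank_z_near_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = location_test(a, a, "rank")
        assert res.method == "rank"
        assert abs(res.statistic) < 0.01

    def test_fully_separated_rank(self):
        res = location_test([1, 2, 3], [10, 20, 30], "rank")
        assert res.statistic < 0  # first group entirely lower
        # U for the lower group is 0: |z| attains its maximum for n=3,3
        assert abs(res.statistic) == pytest.approx(
            (4.5 - 0.5) / math.sqrt(9 * 7 / 12), abs=1e-9
        )

    def test_equal_samples_t_zero(self):
        a = [1.0, 2.0, 3.0]
        res = location_test(a, a, "t")
        assert res.method == "t"
        assert res.statistic == pytest.approx(0.0)

    def test_rank_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 25)
        r1 = location_test(a, b, "rank")
        r2 = location_test(np.exp(a), np.exp(b), "rank")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_auto_picks_rank_for_skewed_data(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 2, 40)
        b = rng.lognormal(0.5, 2, 40)
        assert location_test(a, b, "auto").method == "rank"

    def test_t_requires_two_per_group(self):
        with pytest.raises(ValidationError):
            location_test([1.0], [2.0, 3.0], "t")


def _interaction_frame(slope_a=2.0, slope_b=1.0, noise=0.0, re_sd=0.0,
                       n_animals=4, n_obs=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        grp = "A" if a < n_animals // 2 else "B"
        u = rng.normal(0, re_sd) if re_sd else 0.0
        slope = slope_a if grp == "A" else slope_b
        for _ in range(n_obs):
            x = rng.uniform(0, 10)
            rows.append(
                dict(
                    y=slope * x + u + (rng.normal(0, noise) if noise else 0.0),
                    x=x, genotype=grp, animal=f"m{a}",
                )
            )
    return pd.DataFrame(rows)


class TestFitMixedModel:
    SPEC = MixedModelSpec("y", ("x", "genotype", "x:genotype"), "animal")

    def test_noise_free_interaction_recovered_exactly(self):
        df = _interaction_frame()
        fit = fit_mixed_model(df, self.SPEC)
        # slopes 2 (A) vs 1 (B): the treatment-coded interaction is -1
        inter = [v for k, v in fit.coefficients.items() if ":" in k][0]
        assert inter == pytest.approx(-1.0, abs=1e-6)
        f, _, p = fit.interaction_test
        assert p < 1e-6

    def test_null_interaction_type_one_error_controlled(self):
        # response independent of everything: p > 0.01 in >= 95/100 replicates
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = _interaction_frame(
                slope_a=0, slope_b=0, noise=1.0, re_sd=0.5,
                n_animals=10, n_obs=20, seed=seed,
            )
            fit = fit_mixed_model(df, self.SPEC)
            if fit.interaction_test[2] <= 0.01:
                rejections += 1
        assert rejections <= 5

    def test_single_grouping_level_rejected(self):
        df = _interaction_frame()
        df["animal"] = "same"
        with pytest.raises(ValidationError):
            fit_mixed_model(df, self.SPEC)

    def test_singular_design_rejected_with_diagnostic(self):
        df = _interaction_frame(noise=0.5)
        df["x2"] = df["x"]
        spec = MixedModelSpec("y", ("x", "x2", "genotype", "x:genotype"),
                              "animal")
        with pytest.raises(ValidationError, match="singular"):
            fit_mixed_model(df, spec)

    def test_missing_column_rejected(self):
        df = _interaction_frame()
        with pytest.raises(ValidationError, match="missing"):
            fit_mixed_model(
                df, MixedModelSpec("y", ("licks", "genotype"), "animal")
            )


def _anova_frame(effect=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(12):
        grp = "wt" if a < 6 else "ko"
        for bt in ("bout", "nonbout"):
            base = 0.1
            d = effect if (grp == "ko") == (bt == "nonbout") else -effect
            rows.append(
                dict(dur=base + d + rng.normal(0, noise), bout_type=bt,
                     genotype=grp, animal=f"m{a}")
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_dv_gives_zero_f(self):
        df = _anova_frame(effect=0.0, noise=0.0)
        df["dur"] = 0.1
        res = mixed_anova(df, "dur", "bout_type", "genotype", "animal")
        f_vals = res.table["F"].to_numpy()
        assert np.all(np.nan_to_num(f_vals) == pytest.approx(0.0, abs=1e-9))

    def test_pure_interaction_pattern(self):
        df = _anova_frame(effect=0.05, noise=1e-6, seed=1)
        res = mixed_anova(df, "dur", "bout_type", "genotype", "animal")
        table = res.table.set_index("Source")
        assert table.loc["Interaction", "F"] > 1e6
        assert table.loc["Interaction", "p_unc"] < 1e-6
        # main effects cancel in the +d/-d pattern
        assert table.loc["genotype", "F"] < 1.0
        assert table.loc["bout_type", "F"] < 1.0

    def test_missing_cell_rejected_with_listing(self):
        df = _anova_frame(noise=0.01)
        df = df[~((df["animal"] == "m3") & (df["bout_type"] == "nonbout"))]
        with pytest.raises(ValidationError, match="m3"):
            mixed_anova(df, "dur", "bout_type", "genotype", "animal")


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
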