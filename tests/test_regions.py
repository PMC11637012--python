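"""Size classes, microregion partitions, and cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spheroprofile import regions, synthetic
from spheroprofile.regions import REGIONS


class TestClassifySize:
    @pytest.mark.parametrize("d,expected", [
        (150, "small"), (200, "small"), (200.5, "large"), (400, "large"),
    ])
    def test_class_bounds(self, d, expected):
        assert regions.classify_size(d) == expected

    def test_oversized_warns_and_is_out_of_range(self):
        with pytest.warns(UserWarning, match="out_of_range"):
            assert regions.classify_size(450) == "out_of_range"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            regions.classify_size(0)


class TestBuildPartition:
    def test_small_class_at_80_points(self):
        p = regions.build_partition("small", 80)
        assert p.block_sizes == (20, 40, 20)
        assert p.representative_points == (9, 39, 69)

    def test_large_class_at_80_points(self):
        p = regions.build_partition("large", 80)
        assert p.block_sizes == (48, 24, 8)
        assert p.representative_points == (23, 59, 75)

    def test_smallest_exact_split(self):
        p = regions.build_partition("small", 4)
        assert p.block_sizes == (1, 2, 1)

    @pytest.mark.parametrize("size_class", ["small", "large"])
    @pytest.mark.parametrize("M", [8, 13, 40, 80, 137, 200])
    def test_blocks_contiguous_sum_to_M_fractions_recovered(self, size_class, M):
        p = regions.build_partition(size_class, M)
        assert sum(p.block_sizes) == M
        # three contiguous blocks in core->quiescent->edge order
        changes = np.nonzero(p.labels[:-1] != p.labels[1:])[0]
        assert len(changes) == 2
        assert list(dict.fromkeys(p.labels)) == list(REGIONS)
        for frac, size in zip(p.fractions, p.block_sizes):
            assert abs(size / M - frac) <= 1.0 / M

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            regions.build_partition("medium", 80)


class TestExtractRegions:
    def test_midpoint_on_identity_ramp(self):
        ramp = np.linspace(0, 1, 80)
        p = regions.build_partition("small", 80)
        s = regions.extract_regions(ramp, p, mode="midpoint")
        assert (s.core, s.quiescent, s.edge) == tuple(ramp[[9, 39, 69]])

    def test_block_mean_on_identity_ramp_closed_form(self):
        ramp = np.linspace(0, 1, 80)
        p = regions.build_partition("small", 80)
        s = regions.extract_regions(ramp, p, mode="block_mean")
        assert s.core == pytest.approx(ramp[:20].mean())
        assert s.quiescent == pytest.approx(ramp[20:60].mean())
        assert s.edge == pytest.approx(ramp[60:].mean())

    def test_block_mean_invariant_to_within_block_permutation(self, rng):
        profile = rng.uniform(0, 1, 80)
        p = regions.build_partition("large", 80)
        s1 = regions.extract_regions(profile, p, mode="block_mean")
        shuffled = profile.copy()
        for region in REGIONS:
            idx = np.nonzero(p.labels == region)[0]
            shuffled[idx] = rng.permutation(shuffled[idx])
        s2 = regions.extract_regions(shuffled, p, mode="block_mean")
        assert (s1.core, s1.quiescent, s1.edge) == pytest.approx(
            (s2.core, s2.quiescent, s2.edge))

    def test_degenerate_profile_excluded(self):
        p = regions.build_partition("small", 80)
        s = regions.extract_regions(np.zeros(80), p, degenerate=True)
        assert s.excluded and (s.core, s.quiescent, s.edge) == (0, 0, 0)

    def test_length_mismatch_rejected(self):
        p = regions.build_partition("small", 80)
        with pytest.raises(ValueError):
            regions.extract_regions(np.zeros(40), p)


def balanced_table(rng, means, n=30, sd=0.05):
    rows = []
    for (sc, region), mu in means.items():
        for _ in range(n):
            rows.append({"size_class": sc, "region": region,
                         "value": rng.normal(mu, sd)})
    return pd.DataFrame(rows)


def anova_oracle(table):
    """From-scratch balanced two-way ANOVA sums of squares."""
    y = table["value"].to_numpy()
    grand = y.mean()
    a_levels = sorted(table["region"].unique())
    b_levels = sorted(table["size_class"].unique())
    n = len(table) // (len(a_levels) * len(b_levels))
    ss_a = ss_b = ss_ab = ss_e = 0.0
    a_means = {a: table.loc[table["region"] == a, "value"].mean() for a in a_levels}
    b_means = {b: table.loc[table["size_class"] == b, "value"].mean() for b in b_levels}
    for a in a_levels:
        ss_a += len(b_levels) * n * (a_means[a] - grand) ** 2
    for b in b_levels:
        ss_b += len(a_levels) * n * (b_means[b] - grand) ** 2
    for a in a_levels:
        for b in b_levels:
            cell = table.loc[(table["region"] == a) & (table["size_class"] == b),
                             "value"]
            ss_ab += n * (cell.mean() - a_means[a] - b_means[b] + grand) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(a_levels) * len(b_levels)
    out = {}
    for name, ss, df in [("region", ss_a, df_a), ("size_class", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)]:
        F = (ss / df) / (ss_e / df_e)
        out[name] = {"F": F, "p": float(sps.f.sf(F, df, df_e))}
    return out


class TestCompareRegions:
    def test_strong_separation_gives_tiny_tukey_p(self, rng):
        means = {(sc, r): {"core": 0.8, "quiescent": 0.5, "edge": 0.2}[r]
                 for sc in ("small", "large") for r in REGIONS}
        table = balanced_table(rng, means)
        result = regions.compare_regions(table)
        assert result["anova"]["region"]["p"] < 1e-10
        tukey = result["tukey"]
        ce = tukey[(tukey["scope"] == "size_class=small")
                   & (tukey["group1"] == "core") & (tukey["group2"] == "edge")]
        assert float(ce["p-adj"].iloc[0]) < 1e-4

    def test_matches_from_scratch_sums_of_squares(self, rng):
        means = {(sc, r): rng.uniform(0, 1) for sc in ("small", "large")
                 for r in REGIONS}
        table = balanced_table(rng, means, n=8, sd=0.1)
        result = regions.compare_regions(table)
        oracle = anova_oracle(table)
        for effect in ("region", "size_class", "interaction"):
            assert result["anova"][effect]["F"] == pytest.approx(
                oracle[effect]["F"], abs=1e-10, rel=1e-10)
            assert result["anova"][effect]["p"] == pytest.approx(
                oracle[effect]["p"], abs=1e-10)

    def test_tukey_p_monotone_in_mean_difference(self):
        base = np.array([-0.1, -0.05, 0.0, 0.05, 0.1] * 4)
        rows = []
        for sc in ("small", "large"):
            for region, offset in zip(REGIONS, (0.0, 0.12, 0.3)):
                for v in base:
                    rows.append({"size_class": sc, "region": region,
                                 "value": v + offset})
        result = regions.compare_regions(pd.DataFrame(rows))
        tukey = result["tukey"]
        scope = tukey[tukey["scope"] == "size_class=small"]
        p_by_pair = {(r["group1"], r["group2"]): float(r["p-adj"])
                     for _, r in scope.iterrows()}
        assert p_by_pair[("core", "edge")] <= p_by_pair[("core", "quiescent")]
        assert p_by_pair[("core", "edge")] <= p_by_pair[("edge", "quiescent")]

    def test_zero_variance_reported_degenerate(self):
        rows = [{"size_class": sc, "region": r, "value": 0.5}
                for sc in ("small", "large") for r in REGIONS for _ in range(3)]
        result = regions.compare_regions(pd.DataFrame(rows))
        assert result["degenerate"]

    def test_missing_cell_listed(self, rng):
        means = {(sc, r): 0.5 for sc in ("small", "large") for r in REGIONS}
        table = balanced_table(rng, means, n=3)
        table = table[~((table["size_class"] == "large") & (table["region"] == "edge"))]
        with pytest.raises(ValueError, match="large.*edge"):
            regions.compare_regions(table)


class TestDiameterCorrelation:
    def test_perfect_linear_fit(self):
        x = np.arange(1, 11, dtype=float)
        out = regions.diameter_correlation(x, 2 * x)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)
        assert out["p"] < 1e-6

    def test_small_printed_style_table(self):
        out = regions.diameter_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert out["slope"] == pytest.approx(2.0) and out["r_squared"] == pytest.approx(1.0)

    def test_independent_data_near_zero_r2(self, rng):
        x = rng.uniform(50, 400, 1000)
        y = rng.normal(0.5, 0.1, 1000)
        assert regions.diameter_correlation(x, y)["r_squared"] < 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            regions.diameter_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            regions.diameter_correlation([3, 3, 3], [1, 2, 3])


class TestCohortIntegration:
    def test_reference_cohort_recovers_marker_directions(self):
        table, truth = synthetic.make_cohort(30, 30, seed=11)
        cd80 = table[table["marker"] == "CD80"]
        result = regions.compare_regions(
            cd80[["size_class", "region", "value"]])
        assert result["anova"]["region"]["p"] < 1e-6
        means = cd80.groupby("region", observed=True)["value"].mean()
        assert means["edge"] > means["quiescent"] > means["core"]
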