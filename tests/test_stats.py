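"""Rarefaction, accumulation, occupancy, CDF and Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from soilvirome import simulate, stats


class TestRarefy:
    def test_depth_zero_and_full_depth(self):
        counts = {"a": 3, "b": 2, "c": 1}
        curve = stats.rarefy(counts, [0, 6], n_reps=50, seed=1)
        assert curve.mean_richness[0] == 0.0
        assert curve.mean_richness[1] == 3.0 and curve.sd_richness[1] == 0.0

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            stats.rarefy({"a": 1}, [2], n_reps=5, seed=1)

    def test_hypergeometric_expectation(self):
        # counts {a:2, b:1}, depth 2: E[richness] = 1 + (1 - C(2,2)/C(3,2)) = 5/3
        curve = stats.rarefy({"a": 2, "b": 1}, [2], n_reps=4_000, seed=7)
        expectation = 5 / 3
        se = np.sqrt((2 / 9) / 4_000)  # richness variance is 2/9
        assert abs(curve.mean_richness[0] - expectation) <= 3 * se

    def test_means_monotone_in_depth(self):
        counts = {f"x{i}": i + 1 for i in range(6)}
        total = sum(counts.values())
        curve = stats.rarefy(counts, list(range(0, total + 1, 3)), n_reps=30, seed=5)
        assert all(a <= b + 1e-9 for a, b in zip(curve.mean_richness, curve.mean_richness[1:]))


class TestFilterRarefactionInputs:
    def _matrix(self, richness_per_sample):
        n_attr = max(richness_per_sample) + 1
        data = np.zeros((n_attr, len(richness_per_sample)), int)
        for j, r in enumerate(richness_per_sample):
            data[:r, j] = 1
        return pd.DataFrame(data, columns=[f"s{j}" for j in range(len(richness_per_sample))])

    def test_viral_kind_floor_is_five_strict(self):
        kept, dropped = stats.filter_rarefaction_inputs(self._matrix([4, 5, 9]), "vOTU")
        assert dropped == ["s0"]
        assert list(kept.columns) == ["s1", "s2"]

    def test_host_kind_floor_is_one_hundred(self):
        kept, dropped = stats.filter_rarefaction_inputs(self._matrix([99, 100]), "host_order")
        assert dropped == ["s0"] and list(kept.columns) == ["s1"]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            stats.filter_rarefaction_inputs(self._matrix([1]), "asteroid")


class TestAccumulationCurve:
    def test_unique_attributes_sum_per_sample(self):
        m = pd.DataFrame(np.eye(4, dtype=int), columns=list("abcd"),
                         index=[f"v{i}" for i in range(4)])
        bp = {"a": 10, "b": 20, "c": 30, "d": 40}
        curve = stats.accumulation_curve(m, bp)
        assert list(curve["cumulative_richness"]) == [1, 2, 3, 4]

    def test_identical_samples_flat_after_first(self):
        m = pd.DataFrame(1, index=["v0", "v1"], columns=["a", "b", "c"])
        curve = stats.accumulation_curve(m, {"a": 1, "b": 2, "c": 3})
        assert list(curve["cumulative_richness"]) == [2, 2, 2]

    def test_matches_prefix_union_oracle(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(30, 8)),
                         index=[f"v{i}" for i in range(30)],
                         columns=[f"s{j}" for j in range(8)])
        bp = {f"s{j}": int(rng.integers(1, 1_000)) for j in range(8)}
        curve = stats.accumulation_curve(m, bp)
        order = sorted(m.columns, key=lambda s: (bp[s], s))
        seen = set()
        expected = []
        for s in order:
            seen |= set(m.index[m[s] > 0])
            expected.append(len(seen))
        assert list(curve["cumulative_richness"]) == expected
        assert list(curve["sample_id"]) == order

    def test_missing_assembled_bp_rejected(self):
        m = pd.DataFrame(1, index=["v0"], columns=["a"])
        with pytest.raises(ValueError, match="assembled_bp"):
            stats.accumulation_curve(m, {})


class TestOccupancyStats:
    def test_all_unique(self):
        m = pd.DataFrame(np.eye(5, dtype=int))
        s = stats.occupancy_stats(m)
        assert (s["fraction_gt1_sample"], s["fraction_gt5_samples"]) == (0.0, 0.0)

    def test_two_of_ten_in_two_samples(self):
        data = np.zeros((10, 3), int)
        data[:, 0] = 1
        data[:2, 1] = 1
        s = stats.occupancy_stats(pd.DataFrame(data))
        assert s["fraction_gt1_sample"] == pytest.approx(0.2)

    def test_geometric_fixture_matches_tail(self):
        p = 0.861
        m = simulate.make_occupancy(100, 20_000, ("geometric", {"p": p}), seed=11)
        s = stats.occupancy_stats(m)
        sd = np.sqrt(p * (1 - p) / 20_000)
        assert abs(s["fraction_gt1_sample"] - (1 - p)) <= 3 * sd


class TestHostRatioCdf:
    def test_step_at_zero(self):
        cdf = stats.host_ratio_cdf([0.0, 0.0, 1.0])
        assert cdf.set_index("ratio").loc[0.0, "cdf"] == pytest.approx(2 / 3)

    def test_single_sample(self):
        cdf = stats.host_ratio_cdf([0.25])
        assert cdf.values.tolist() == [[0.25, 1.0]]

    def test_matches_sort_based_oracle(self, rng):
        ratios = rng.uniform(0, 2, size=40).round(2).tolist()
        cdf = stats.host_ratio_cdf(ratios)
        xs = np.sort(ratios)
        for _, row in cdf.iterrows():
            assert row["cdf"] == pytest.approx((xs <= row["ratio"]).mean())

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            stats.host_ratio_cdf([-0.1])


def spearman_oracle(x, y):
    """Direct definition: Pearson correlation of average ranks."""
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearmanHostEnv:
    def _frames(self, counts, env_vals):
        samples = [f"s{i}" for i in range(len(counts))]
        hc = pd.DataFrame([counts], index=["orderA"], columns=samples)
        env = pd.DataFrame({"ph": env_vals}, index=samples)
        return hc, env

    def test_perfectly_monotone_pair(self):
        hc, env = self._frames([1, 2, 3, 4, 5, 6, 7], [2.0, 2.5, 3.0, 4.0, 5.5, 6.0, 7.5])
        rho = stats.spearman_host_env(hc, env, min_samples=5)
        assert rho.loc["orderA", "ph"] == pytest.approx(1.0)

    def test_constant_vector_missing(self):
        hc, env = self._frames([2] * 7, [1, 2, 3, 4, 5, 6, 7])
        rho = stats.spearman_host_env(hc, env, min_samples=5)
        assert np.isnan(rho.loc["orderA", "ph"])

    def test_prevalence_filter_is_strict(self):
        hc, env = self._frames([1, 1, 1, 1, 1, 0, 0], [1, 2, 3, 4, 5, 6, 7])
        rho = stats.spearman_host_env(hc, env, min_samples=5)
        assert rho.empty  # present in exactly 5 samples -> excluded

    def test_tie_heavy_fixture_matches_rank_formula(self):
        counts = [3, 3, 0, 1, 5, 1]
        envv = [4.0, 4.0, 6.1, 5.0, 4.8, 5.0]
        hc, env = self._frames(counts, envv)
        rho = stats.spearman_host_env(hc, env, min_samples=1)
        assert rho.loc["orderA", "ph"] == pytest.approx(spearman_oracle(counts, envv))
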