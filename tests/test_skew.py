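import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from initdir.intervals import IAR
from initdir.signal import CoverageTrack, aggregate_over_regions
from initdir.intervals import Region, RegionSet, flanks_from_midpoint
from initdir.skew import (
    LocusSkew,
    compute_locus_skews,
    export_skew_violin_data,
    filter_silent,
    wilcoxon_rank_sum,
)
from initdir.skew import test_directionality as directionality_test


def _iar(start, end, chrom="c"):
    return IAR(chrom, start, end, "g", "+", "upstream-of-gene", 500)


def brute_force_p(x, y):
    """Enumerate all rank splits of the pooled sample (midranks for ties)."""
    pooled = np.concatenate([x, y])
    n1, N = len(x), len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    sv = pooled[order]
    i = 0
    while i < N:
        j = i
        while j + 1 < N and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1
        i = j + 1
    mu = n1 * ranks.sum() / N
    w_obs = ranks[:n1].sum()
    count = total = 0
    for comb in itertools.combinations(range(N), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        _, p = wilcoxon_rank_sum([5.0] * 4, [5.0] * 6)
        assert p == 1.0

    def test_fully_separated_triples_give_exact_p_of_one_tenth(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 8, 2)
        if rng.random() < 0.5:
            x, y = rng.normal(size=int(n1)), rng.normal(size=int(n2))
        else:  # tied integer data exercises midranks
            x = rng.integers(0, 4, int(n1)).astype(float)
            y = rng.integers(0, 4, int(n2)).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(brute_force_p(x, y), abs=1e-12)

    def test_asymptotic_branch_cross_checked_against_scipy(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1, 35)
        _, p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 28)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(2 * x + 1, 2 * y + 1)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestLocusSkews:
    def test_symmetric_signal_gives_zero_skew(self):
        track = CoverageTrack({"c": np.full(20_000, 4.0)})
        (locus,) = compute_locus_skews(track, [_iar(9_900, 10_100)])
        assert locus.skew == pytest.approx(0.0)

    def test_skew_formula_log2_plus_one(self):
        v = np.zeros(20_000)
        v[10_000:12_000] = 7.0
        track = CoverageTrack({"c": v})
        (locus,) = compute_locus_skews(track, [_iar(9_950, 10_050)])
        assert locus.up_signal == 0.0
        assert locus.down_signal == pytest.approx(7.0)
        assert locus.skew == pytest.approx(math.log2(8) - math.log2(1))

    def test_matches_independent_flank_aggregation(self):
        rng = np.random.default_rng(14)
        track = CoverageTrack({"c": rng.poisson(3.0, 30_000).astype(float)})
        iars = [_iar(5_000, 5_200), _iar(12_345, 12_400), _iar(25_000, 25_300)]
        loci = compute_locus_skews(track, iars)
        for iar, locus in zip(iars, loci):
            up, down, _ = flanks_from_midpoint(iar)
            sig = aggregate_over_regions(track, [up, down])
            assert locus.up_signal == pytest.approx(sig[0].mean_signal)
            assert locus.down_signal == pytest.approx(sig[1].mean_signal)

    def test_oriented_mode_uses_minus_upstream_plus_downstream(self):
        plus = CoverageTrack({"c": np.full(20_000, 2.0)}, strand="+")
        minus = CoverageTrack({"c": np.full(20_000, 6.0)}, strand="-")
        (locus,) = compute_locus_skews((plus, minus), [_iar(9_900, 10_100)],
                                       strand_mode="oriented")
        assert locus.up_signal == pytest.approx(6.0)
        assert locus.down_signal == pytest.approx(2.0)

    def test_oriented_mode_requires_strand_pair(self):
        track = CoverageTrack({"c": np.zeros(100)})
        with pytest.raises(ValueError, match="oriented"):
            compute_locus_skews(track, [_iar(40, 60)], strand_mode="oriented")


class TestFilterSilent:
    def test_zero_both_sides_removed_one_sided_kept(self):
        loci = [LocusSkew("a", 0.0, 0.0), LocusSkew("b", 0.0, 5.0), LocusSkew("c", 1.0, 1.0)]
        kept = filter_silent(loci)
        assert [l.iar_id for l in kept] == ["b", "c"]

    @pytest.mark.parametrize("seed", range(3))
    def test_survivor_count_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        loci = [
            LocusSkew(str(i), float(rng.integers(0, 3)), float(rng.integers(0, 3)))
            for i in range(100)
        ]
        kept = filter_silent(loci)
        assert len(kept) == sum(1 for l in loci if max(l.up_signal, l.down_signal) > 0)


class TestDirectionality:
    def _loci(self, rng, n, up_mean, down_mean, prefix="L"):
        return [
            LocusSkew(f"{prefix}{i}", float(rng.poisson(up_mean)), float(rng.poisson(down_mean)))
            for i in range(n)
        ]

    def test_extreme_separation_called_unidirectional_downstream(self):
        rng = np.random.default_rng(15)
        loci = self._loci(rng, 200, 1.0, 50.0)
        groups = {l.iar_id: "g" for l in loci}
        (res,) = directionality_test(loci, groups)
        assert res.significant and res.call == "unidirectional"
        assert res.favored_side == "downstream"

    def test_bonferroni_threshold_splits_alpha_across_groups(self):
        rng = np.random.default_rng(16)
        loci = self._loci(rng, 50, 5, 5, "a") + self._loci(rng, 50, 5, 5, "b")
        groups = {l.iar_id: l.iar_id[0] for l in loci}
        results = directionality_test(loci, groups, alpha=0.05)
        assert all(r.bonferroni_threshold == pytest.approx(0.025) for r in results)
        assert all(r.m_tests == 2 for r in results)

    def test_small_groups_reported_as_insufficient_data(self):
        rng = np.random.default_rng(17)
        loci = self._loci(rng, 5, 5, 5)
        (res,) = directionality_test(loci, {l.iar_id: "g" for l in loci}, min_n=10)
        assert res.call == "insufficient data"
        assert math.isnan(res.p_value)

    def test_all_silent_group_is_insufficient_not_an_exception(self):
        loci = [LocusSkew(f"s{i}", 0.0, 0.0) for i in range(20)]
        (res,) = directionality_test(loci, {l.iar_id: "g" for l in loci})
        assert res.call == "insufficient data"

    def test_swapping_sides_flips_call_and_preserves_p(self):
        rng = np.random.default_rng(18)
        loci = self._loci(rng, 120, 2.0, 9.0)
        swapped = [LocusSkew(l.iar_id, l.down_signal, l.up_signal) for l in loci]
        groups = {l.iar_id: "g" for l in loci}
        (a,) = directionality_test(loci, groups)
        (b,) = directionality_test(swapped, groups)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert {a.favored_side, b.favored_side} == {"upstream", "downstream"}

    def test_significant_iff_p_below_threshold_invariant(self):
        rng = np.random.default_rng(19)
        loci = self._loci(rng, 60, 4, 6, "a") + self._loci(rng, 60, 5, 5, "b")
        groups = {l.iar_id: l.iar_id[0] for l in loci}
        for r in directionality_test(loci, groups):
            if r.call != "insufficient data":
                assert r.significant == (r.p_value < r.bonferroni_threshold)
                assert (r.favored_side == "none") == (r.call == "bidirectional")


class TestViolinExport:
    def test_two_loci_give_four_rows(self):
        loci = [LocusSkew("a", 1.0, 2.0), LocusSkew("b", 0.0, 3.0)]
        table = export_skew_violin_data(loci, {"a": "g", "b": "g"})
        assert len(table) == 4
        assert set(table["side"]) == {"up", "down"}

    def test_empty_input_gives_empty_table_with_header(self):
        table = export_skew_violin_data([])
        assert len(table) == 0
        assert list(table.columns) == ["group", "locus", "side", "log_value"]

    @pytest.mark.parametrize("sizes", [(3, 5), (1, 1, 7)])
    def test_row_count_is_twice_total_group_sizes(self, sizes):
        loci, groups = [], {}
        for g, n in enumerate(sizes):
            for i in range(n):
                lid = f"g{g}_{i}"
                loci.append(LocusSkew(lid, 1.0, 1.0))
                groups[lid] = f"g{g}"
        table = export_skew_violin_data(loci, groups)
        assert len(table) == 2 * sum(sizes)


def test_plot_violin_renders_without_error():
    import matplotlib

    matplotlib.use("Agg")
    from initdir.skew import plot_violin

    loci = [LocusSkew(f"l{i}", float(i), float(2 * i)) for i in range(6)]
    table = export_skew_violin_data(loci, {l.iar_id: "g" for l in loci})
    ax = plot_violin(table)
    assert ax.get_ylabel() == "log2(signal + 1)"
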