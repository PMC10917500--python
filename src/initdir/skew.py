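"""Upstream/downstream transcription skew at intergenic accessible regions.

For each IAR, mean nascent signal is computed over the 2 kb flanks on
either side of the region midpoint, log2(x+1)-transformed, and compared
between sides per group (cluster) with a two-sided Wilcoxon rank-sum test
under a Bonferroni family-wise threshold.  Significant groups are called
unidirectional (favored side = larger median); non-significant groups
with signal are called bidirectional.  Loci with zero signal on both
sides are excluded before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .clustering import ClusterAssignment
from .intervals import IAR, Region, flanks_from_midpoint
from .signal import CoverageTrack


@dataclass
class LocusSkew:
    """Per-IAR flank signal pair; skew = down_log - up_log."""

    iar_id: str
    up_signal: float
    down_signal: float

    @property
    def up_log(self) -> float:
        return math.log2(self.up_signal + 1.0)

    @property
    def down_log(self) -> float:
        return math.log2(self.down_signal + 1.0)

    @property
    def skew(self) -> float:
        return self.down_log - self.up_log


@dataclass
class SkewTestResult:
    """One group's rank-sum test and directionality call."""

    group: str
    n_loci: int
    statistic: float
    p_value: float
    alpha: float
    m_tests: int
    bonferroni_threshold: float
    significant: bool
    call: str  # unidirectional | bidirectional | insufficient data
    favored_side: str  # upstream | downstream | none


def compute_locus_skews(
    tracks: CoverageTrack | tuple[CoverageTrack, CoverageTrack],
    iars: Sequence[IAR | Region],
    flank: int = 2000,
    strand_mode: str = "combined",
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[LocusSkew]:
    """Mean0 flank signal on both sides of each IAR midpoint.

    ``strand_mode="combined"`` sums plus and minus nascent tracks (or uses
    a single unstranded track) on both sides; ``"oriented"`` requires a
    (plus, minus) pair and assigns the minus-strand track to the upstream
    side and the plus-strand track to the downstream side, matching the
    geometry of divergent initiation.
    """
    if strand_mode not in ("combined", "oriented"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if isinstance(tracks, CoverageTrack):
        if strand_mode == "oriented":
            raise ValueError("oriented mode requires a (plus, minus) track pair")
        up_track = down_track = tracks
    else:
        plus, minus = tracks
        if strand_mode == "combined":
            up_track = down_track = plus + minus
        else:
            up_track, down_track = minus, plus
    out = []
    for iar in iars:
        size = chrom_sizes.get(iar.chrom) if chrom_sizes else None
        up, down, _ = flanks_from_midpoint(iar, flank=flank, chrom_size=size)
        up_mean = up_track.mean(up.chrom, up.start, up.end)
        down_mean = down_track.mean(down.chrom, down.start, down.end)
        name = iar.name if iar.name is not None else f"{iar.chrom}:{iar.start}-{iar.end}"
        out.append(LocusSkew(iar_id=name, up_signal=up_mean, down_signal=down_mean))
    return out


def filter_silent(loci: Iterable[LocusSkew]) -> list[LocusSkew]:
    """Drop loci with zero signal on BOTH sides (uninformative for skew)."""
    return [l for l in loci if not (l.up_signal == 0 and l.down_signal == 0)]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled), dtype=np.float64)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_two_sided_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Exact two-sided p over all C(N, n1) rank splits via subset-sum DP.

    Midranks are doubled to integers so counts are exact.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    N = len(r2)
    total2 = int(r2.sum())
    max_sum = total2
    # dp[k, s] = number of k-subsets of the first i ranks with doubled-sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(min(n1, N), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[n1]
    mu2 = n1 * total2 / N
    obs_dev = abs(2.0 * w_obs - mu2)
    sums = np.arange(max_sum + 1, dtype=np.float64)
    extreme = np.abs(sums - mu2) >= obs_dev - 1e-9
    n_total = counts.sum()
    return float(min(1.0, counts[extreme].sum() / n_total))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of ``x``, two-sided p).  Below a combined sample
    size of ``exact_threshold`` the null distribution is enumerated
    exactly over all rank splits (ties handled via midranks); above it, a
    normal approximation with tie correction and continuity correction is
    used.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    N = n1 + n2
    if np.all(pooled == pooled[0]):
        return u, 1.0
    if N <= exact_threshold:
        p = _exact_two_sided_p(ranks, n1, w)
        return u, p
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    dev = abs(u - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return u, p


# ---------------------------------------------------------------------------
# Group-level directionality testing
# ---------------------------------------------------------------------------

def test_directionality(
    loci: Sequence[LocusSkew],
    groups: ClusterAssignment | Mapping[str, int | str],
    alpha: float = 0.05,
    min_n: int = 10,
    paired: bool = False,
) -> list[SkewTestResult]:
    """Per-group up vs down rank-sum test with Bonferroni correction.

    ``groups`` maps locus id -> group label.  Within each group the
    up_log values form one sample and the down_log values the other
    (two-sample rank-sum, as in the published analysis; ``paired=True``
    switches to the Wilcoxon signed-rank variant).  The Bonferroni
    divisor ``m`` is the number of groups actually tested in this call;
    groups with fewer than ``min_n`` loci after silent-locus filtering
    are reported as "insufficient data" and do not count toward ``m``.
    """
    mapping = groups.labels if isinstance(groups, ClusterAssignment) else dict(groups)
    by_group: dict[str, list[LocusSkew]] = {}
    for locus in loci:
        if locus.iar_id not in mapping:
            raise ValueError(f"locus {locus.iar_id} has no group assignment")
        by_group.setdefault(str(mapping[locus.iar_id]), []).append(locus)

    filtered = {g: filter_silent(ls) for g, ls in by_group.items()}
    testable = [g for g, ls in sorted(filtered.items()) if len(ls) >= min_n]
    m = len(testable)
    threshold = alpha / m if m else float("nan")

    results = []
    for g in sorted(filtered):
        ls = filtered[g]
        n = len(ls)
        if n < min_n:
            results.append(
                SkewTestResult(
                    group=g,
                    n_loci=n,
                    statistic=float("nan"),
                    p_value=float("nan"),
                    alpha=alpha,
                    m_tests=m,
                    bonferroni_threshold=threshold,
                    significant=False,
                    call="insufficient data",
                    favored_side="none",
                )
            )
            continue
        up = np.array([l.up_log for l in ls])
        down = np.array([l.down_log for l in ls])
        if paired:
            from scipy.stats import wilcoxon as signed_rank

            diff = down - up
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = signed_rank(down, up, zero_method="wilcox")
        else:
            stat, p = wilcoxon_rank_sum(up, down)
        significant = p < threshold
        if significant:
            med_up, med_down = float(np.median(up)), float(np.median(down))
            if med_down == med_up:  # degenerate tie: fall back to means
                med_up, med_down = float(np.mean(up)), float(np.mean(down))
            favored = "downstream" if med_down > med_up else "upstream"
            call = "unidirectional"
        else:
            favored = "none"
            call = "bidirectional"
        results.append(
            SkewTestResult(
                group=g,
                n_loci=n,
                statistic=float(stat),
                p_value=float(p),
                alpha=alpha,
                m_tests=m,
                bonferroni_threshold=threshold,
                significant=significant,
                call=call,
                favored_side=favored,
            )
        )
    return results


def results_frame(results: Sequence[SkewTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "n_loci": r.n_loci,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "alpha": r.alpha,
                "m_tests": r.m_tests,
                "bonferroni_threshold": r.bonferroni_threshold,
                "significant": r.significant,
                "call": r.call,
                "favored_side": r.favored_side,
            }
            for r in results
        ]
    )


def loci_frame(loci: Sequence[LocusSkew]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "iar": l.iar_id,
                "up_signal": l.up_signal,
                "down_signal": l.down_signal,
                "up_log": l.up_log,
                "down_log": l.down_log,
                "skew": l.skew,
            }
            for l in loci
        ]
    )


def export_skew_violin_data(
    loci: Sequence[LocusSkew],
    groups: ClusterAssignment | Mapping[str, int | str] | None = None,
) -> pd.DataFrame:
    """Long-format (group, side, log_value) table for violin plotting."""
    mapping = (
        groups.labels
        if isinstance(groups, ClusterAssignment)
        else dict(groups)
        if groups is not None
        else {}
    )
    rows = []
    for l in loci:
        g = str(mapping.get(l.iar_id, "all"))
        rows.append({"group": g, "locus": l.iar_id, "side": "up", "log_value": l.up_log})
        rows.append({"group": g, "locus": l.iar_id, "side": "down", "log_value": l.down_log})
    return pd.DataFrame(rows, columns=["group", "locus", "side", "log_value"])


def plot_violin(table: pd.DataFrame, ax=None):
    """Violin plot of up/down log-signal per group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = sorted(table["group"].unique())
    data, positions, labels = [], [], []
    pos = 0
    for g in groups:
        for side in ("up", "down"):
            vals = table.loc[(table["group"] == g) & (table["side"] == side), "log_value"]
            data.append(vals.to_numpy())
            positions.append(pos)
            labels.append(f"{g}\n{side}")
            pos += 1
        pos += 1
    ax.violinplot([d if len(d) else [0.0] for d in data], positions=positions, showmedians=True)
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("log2(signal + 1)")
    return ax
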