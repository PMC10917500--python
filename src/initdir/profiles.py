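"""Anchored and scaled-gene-body metaprofiles.

Builds regions x bins signal matrices (TSS/midpoint-anchored windows or
scaled gene bodies with fixed flanks) and summarizes them into mean / SE /
95% CI curves, optionally z-score normalized and with two-sided trimming
of each bin's value distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel
from .signal import CoverageTrack, trim_extremes


@dataclass
class ProfileMatrix:
    """Regions x bins signal matrix with anchoring metadata.

    Rows follow the input region order.  When ``strand_oriented`` is true,
    rows of minus-strand anchors have been reversed so that bin 0 is the
    biologically upstream end.  Out-of-chromosome bins are NaN and are
    excluded from summaries.
    """

    matrix: np.ndarray
    region_ids: list[str]
    anchoring: str  # "point-anchored" | "scaled-body"
    bin_size: int
    upstream_bp: int
    downstream_bp: int
    track_label: str = ""
    strand_oriented: bool = False
    body_bins: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.region_ids) != self.matrix.shape[0]:
            raise ValueError("region_ids length must match row count")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV (rows = regions) with a JSON metadata sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.matrix, index=self.region_ids)
        df.index.name = "region"
        df.to_csv(path, sep="\t", float_format="%.10g")
        meta = {
            "anchoring": self.anchoring,
            "bin_size": self.bin_size,
            "upstream_bp": self.upstream_bp,
            "downstream_bp": self.downstream_bp,
            "track_label": self.track_label,
            "strand_oriented": self.strand_oriented,
            "body_bins": self.body_bins,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            matrix=df.to_numpy(dtype=np.float64),
            region_ids=[str(i) for i in df.index],
            **meta,
        )


@dataclass
class ProfileSummary:
    """Per-bin mean, SE and normal-approximation 95% CI of a profile matrix."""

    mean: np.ndarray
    se: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_regions: np.ndarray
    zscored: bool = False
    track_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(len(self.mean)),
                "mean": self.mean,
                "se": self.se,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "n_regions": self.n_regions,
            }
        )


def _bin_means(track: CoverageTrack, chrom: str, window_start: int, n_bins: int, bin_size: int) -> np.ndarray:
    """Means of consecutive bins; bins extending beyond the chromosome are NaN."""
    out = np.empty(n_bins, dtype=np.float64)
    if chrom not in track.values:
        out.fill(np.nan)
        return out
    n = track.chrom_length(chrom)
    for j in range(n_bins):
        s = window_start + j * bin_size
        e = s + bin_size
        if s < 0 or e > n:
            out[j] = np.nan
        else:
            out[j] = track.sum(chrom, s, e) / bin_size
    return out


def point_anchored_matrix(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    bin_size: int = 50,
    region_ids: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Signal matrix around anchor points (TSSs or IAR midpoints).

    Row r, bin j is the mean signal in
    ``[pos - upstream + j*bin, pos - upstream + (j+1)*bin)`` for a
    plus-strand anchor; minus-strand rows are mirrored so bin 0 is
    biologically upstream.
    """
    if upstream_bp % bin_size or downstream_bp % bin_size:
        raise ValueError("bin_size must divide upstream_bp and downstream_bp")
    n_bins = (upstream_bp + downstream_bp) // bin_size
    rows = np.empty((len(anchors), n_bins), dtype=np.float64)
    for i, (chrom, pos, strand) in enumerate(anchors):
        if strand == "-":
            row = _bin_means(track, chrom, pos - downstream_bp, n_bins, bin_size)[::-1]
        else:
            row = _bin_means(track, chrom, pos - upstream_bp, n_bins, bin_size)
        rows[i] = row
    ids = (
        list(region_ids)
        if region_ids is not None
        else [f"{c}:{p}({s})" for c, p, s in anchors]
    )
    return ProfileMatrix(
        matrix=rows,
        region_ids=ids,
        anchoring="point-anchored",
        bin_size=bin_size,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        track_label=track.label,
        strand_oriented=True,
    )


def scaled_body_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> ProfileMatrix:
    """TSS-flank / scaled-body / TES-flank matrix.

    Flanks are binned at ``flank_bin`` bp; each gene body is resampled to
    exactly ``body_bins`` bins by averaging over equal-length sub-intervals
    with fractional base weighting at the edges.  Minus-strand genes are
    orientation-flipped so every row runs 5'→3'.
    """
    if flank_bp % flank_bin:
        raise ValueError("flank_bin must divide flank_bp")
    n_flank = flank_bp // flank_bin
    n_bins = 2 * n_flank + body_bins
    rows = np.empty((len(genes), n_bins), dtype=np.float64)
    for i, g in enumerate(genes):
        up = _bin_means(track, g.chrom, g.start - flank_bp, n_flank, flank_bin)
        down = _bin_means(track, g.chrom, g.end, n_flank, flank_bin)
        L = g.end - g.start
        edges = g.start + L * np.arange(body_bins + 1) / body_bins
        body = np.empty(body_bins, dtype=np.float64)
        for j in range(body_bins):
            width = edges[j + 1] - edges[j]
            body[j] = track.integral(g.chrom, edges[j], edges[j + 1]) / width
        row = np.concatenate([up, body, down])
        if g.strand == "-":
            row = row[::-1]
        rows[i] = row
    return ProfileMatrix(
        matrix=rows,
        region_ids=[g.gene_id for g in genes],
        anchoring="scaled-body",
        bin_size=flank_bin,
        upstream_bp=flank_bp,
        downstream_bp=flank_bp,
        track_label=track.label,
        strand_oriented=True,
        body_bins=body_bins,
    )


def crop_matrix(matrix: ProfileMatrix, upstream_bp: int, downstream_bp: int) -> ProfileMatrix:
    """Restrict a point-anchored matrix to a narrower window around the anchor.

    Used to cluster on the element-intrinsic core of the window while the
    full window is kept for display.
    """
    if matrix.anchoring != "point-anchored":
        raise ValueError("crop_matrix only applies to point-anchored matrices")
    if upstream_bp > matrix.upstream_bp or downstream_bp > matrix.downstream_bp:
        raise ValueError("crop window exceeds matrix extent")
    if upstream_bp % matrix.bin_size or downstream_bp % matrix.bin_size:
        raise ValueError("crop extents must be multiples of the bin size")
    anchor_bin = matrix.upstream_bp // matrix.bin_size
    lo = anchor_bin - upstream_bp // matrix.bin_size
    hi = anchor_bin + downstream_bp // matrix.bin_size
    return ProfileMatrix(
        matrix=matrix.matrix[:, lo:hi],
        region_ids=list(matrix.region_ids),
        anchoring=matrix.anchoring,
        bin_size=matrix.bin_size,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        track_label=matrix.track_label,
        strand_oriented=matrix.strand_oriented,
        body_bins=matrix.body_bins,
    )


def summarize_profile(
    matrix: ProfileMatrix,
    zscore: bool = True,
    trim: tuple[float, float] = (0.0, 0.0),
) -> ProfileSummary:
    """Mean / SE / 95% CI curves of a profile matrix.

    ``trim=(l, u)`` applies a two-sided trim to each bin's value
    distribution before averaging (the nascent-data artifact guard).  With
    ``zscore`` the mean, SE and CI curves are jointly transformed by
    subtracting the mean of the per-bin means and dividing by their
    standard deviation, so the mean curve has mean 0 and sd 1 across bins.
    """
    m = matrix.matrix
    if m.size == 0:
        raise ValueError("empty profile matrix")
    n_bins = m.shape[1]
    mean = np.empty(n_bins)
    se = np.empty(n_bins)
    n_regions = np.empty(n_bins, dtype=int)
    for j in range(n_bins):
        col = m[:, j]
        col = col[~np.isnan(col)]
        if trim != (0.0, 0.0):
            col = trim_extremes(col, *trim)
        n = len(col)
        n_regions[j] = n
        if n == 0:
            mean[j], se[j] = np.nan, np.nan
        else:
            mean[j] = col.mean()
            se[j] = col.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    ci_low = mean - 1.96 * se
    ci_high = mean + 1.96 * se
    zscored = False
    if zscore:
        valid = ~np.isnan(mean)
        mu = float(np.mean(mean[valid]))
        sd = float(np.std(mean[valid]))
        if sd > 0:
            mean = (mean - mu) / sd
            se = se / sd
            ci_low = (ci_low - mu) / sd
            ci_high = (ci_high - mu) / sd
            zscored = True
    return ProfileSummary(
        mean=mean,
        se=se,
        ci95_low=ci_low,
        ci95_high=ci_high,
        n_regions=n_regions,
        zscored=zscored,
        track_label=matrix.track_label,
    )


def plot_summary(summary: ProfileSummary, ax=None, label: str | None = None):
    """Metaplot rendering: mean line with SE and CI95 shading."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(summary.mean))
    ax.fill_between(x, summary.ci95_low, summary.ci95_high, alpha=0.2, linewidth=0)
    ax.fill_between(
        x, summary.mean - summary.se, summary.mean + summary.se, alpha=0.4, linewidth=0
    )
    ax.plot(x, summary.mean, label=label or summary.track_label)
    ax.set_xlabel("bin")
    ax.set_ylabel("signal" + (" (z-score)" if summary.zscored else ""))
    return ax
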