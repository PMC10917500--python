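"""Coverage-track access, normalization, and per-interval aggregation.

A :class:`CoverageTrack` holds per-base signal as one numpy array per
chromosome.  Interval means follow the bigWigAverageOverBed "mean0"
convention: every base of the interval contributes, uncovered bases as
zero.  Tracks read from bedGraph or bigWig; bedGraph is the
dependency-light round-trip format used by the synthetic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import Region, RegionSet


class TrackFormatError(ValueError):
    pass


@dataclass
class RegionSignal:
    """mean0 signal of one region; n_covered_bases counts bases with signal > 0."""

    name: str
    mean_signal: float
    n_covered_bases: int


class CoverageTrack:
    """Per-base numeric signal over a genome, optionally strand-specific.

    Parameters
    ----------
    values
        Mapping chromosome -> per-base float array.
    strand
        "+", "-", or "unstranded".
    bin_size
        Native resolution (bp) the signal was generated/counted at; only
        used as the default bin length for RPKM normalization.
    """

    def __init__(
        self,
        values: dict[str, np.ndarray],
        strand: str = "unstranded",
        label: str = "",
        normalization: str = "raw",
        bin_size: int = 1,
    ) -> None:
        if strand not in ("+", "-", "unstranded"):
            raise ValueError(f"bad strand {strand!r}")
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in values.items()}
        for c, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values on {c}")
        self.strand = strand
        self.label = label
        self.normalization = normalization
        self.bin_size = int(bin_size)
        self._cumsum: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom])

    def _cs(self, chrom: str) -> np.ndarray:
        cs = self._cumsum.get(chrom)
        if cs is None:
            cs = np.concatenate([[0.0], np.cumsum(self.values[chrom])])
            self._cumsum[chrom] = cs
        return cs

    def sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end) ∩ chromosome."""
        if chrom not in self.values:
            warnings.warn(f"query on unknown chromosome {chrom}; returning 0", stacklevel=2)
            return 0.0
        n = self.chrom_length(chrom)
        lo, hi = max(0, start), min(end, n)
        if lo >= hi:
            return 0.0
        cs = self._cs(chrom)
        return float(cs[hi] - cs[lo])

    def mean(self, chrom: str, start: int, end: int) -> float:
        """mean0 over [start, end): bases outside the chromosome count as 0."""
        if end <= start:
            raise ValueError("zero-width query")
        return self.sum(chrom, start, end) / (end - start)

    def integral(self, chrom: str, x0: float, x1: float) -> float:
        """Integral of the per-base step function over real interval [x0, x1)."""
        if chrom not in self.values:
            return 0.0
        v = self.values[chrom]
        cs = self._cs(chrom)
        n = len(v)

        def F(x: float) -> float:
            x = min(max(x, 0.0), float(n))
            i = int(x)
            if i >= n:
                return float(cs[n])
            return float(cs[i]) + (x - i) * float(v[i])

        return F(x1) - F(x0)

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if set(self.values) != set(other.values):
            raise ValueError("tracks cover different chromosomes")
        vals = {}
        for c in self.values:
            if len(self.values[c]) != len(other.values[c]):
                raise ValueError(f"length mismatch on {c}")
            vals[c] = self.values[c] + other.values[c]
        return CoverageTrack(
            vals,
            strand="unstranded",
            label=f"{self.label}+{other.label}",
            normalization=self.normalization,
            bin_size=self.bin_size,
        )

    # -- I/O ----------------------------------------------------------------

    def write_bedgraph(self, path: str | Path) -> None:
        """Run-length-encoded bedGraph; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in self.values:
                v = self.values[chrom]
                if len(v) == 0:
                    continue
                change = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(v)]])
                for s, e in zip(starts, ends):
                    val = v[s]
                    if val != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{val:.10g}\n")

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_sizes: dict[str, int] | None = None,
        strand: str = "unstranded",
        label: str = "",
        bin_size: int = 1,
    ) -> "CoverageTrack":
        entries: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                if len(f) < 4:
                    raise TrackFormatError(f"{path}:{i}: expected 4 bedGraph columns")
                try:
                    s, e, val = int(f[1]), int(f[2]), float(f[3])
                except ValueError as exc:
                    raise TrackFormatError(f"{path}:{i}: {exc}") from exc
                entries.setdefault(f[0], []).append((s, e, val))
        values: dict[str, np.ndarray] = {}
        sizes = dict(chrom_sizes or {})
        for chrom, ivs in entries.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise TrackFormatError(f"overlapping bedGraph intervals on {chrom}")
            n = sizes.get(chrom, max(e for _, e, _ in ivs))
            arr = np.zeros(n, dtype=np.float64)
            for s, e, val in ivs:
                arr[s : min(e, n)] = val
            values[chrom] = arr
        for chrom, n in sizes.items():
            values.setdefault(chrom, np.zeros(n, dtype=np.float64))
        return cls(values, strand=strand, label=label or str(path), bin_size=bin_size)

    @classmethod
    def from_bigwig(
        cls,
        path: str | Path,
        strand: str = "unstranded",
        label: str = "",
        bin_size: int = 1,
    ) -> "CoverageTrack":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        try:
            values = {}
            for chrom, n in bw.chroms().items():
                arr = np.nan_to_num(
                    np.asarray(bw.values(chrom, 0, n), dtype=np.float64), nan=0.0
                )
                values[chrom] = arr
        finally:
            bw.close()
        return cls(values, strand=strand, label=label or str(path), bin_size=bin_size)


def load_track(
    path: str | Path,
    format: str | None = None,
    strand: str = "unstranded",
    chrom_sizes: dict[str, int] | None = None,
    label: str = "",
    bin_size: int = 1,
) -> CoverageTrack:
    """Load a coverage track, auto-detecting bigWig vs bedGraph by suffix."""
    path = Path(path)
    if format is None:
        format = "bigwig" if path.suffix.lower() in (".bw", ".bigwig") else "bedgraph"
    if format == "bigwig":
        return CoverageTrack.from_bigwig(path, strand=strand, label=label, bin_size=bin_size)
    if format == "bedgraph":
        return CoverageTrack.from_bedgraph(
            path, chrom_sizes=chrom_sizes, strand=strand, label=label, bin_size=bin_size
        )
    raise ValueError(f"unknown track format {format!r}")


def rpkm_normalize(
    track: CoverageTrack, total_reads: int, bin_length: int | None = None
) -> CoverageTrack:
    """Scale raw binned counts to reads-per-kilobase-per-million.

    Follows the deepTools bamCoverage convention
    ``rpkm = count * 1e9 / (bin_length_bp * total_reads)``.  ``bin_length``
    defaults to the track's native bin size.
    """
    if track.normalization != "raw":
        raise ValueError("track is already normalized")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    bl = bin_length if bin_length is not None else track.bin_size
    factor = 1e9 / (bl * total_reads)
    return CoverageTrack(
        {c: v * factor for c, v in track.values.items()},
        strand=track.strand,
        label=track.label,
        normalization="rpkm",
        bin_size=track.bin_size,
    )


def aggregate_over_regions(
    track: CoverageTrack, regions: RegionSet | Iterable[Region]
) -> list[RegionSignal]:
    """Per-region mean0 signal (bigWigAverageOverBed semantics)."""
    out = []
    for r in regions:
        if r.end <= r.start:
            raise ValueError(f"zero-width region {r}")
        mean = track.mean(r.chrom, r.start, r.end)
        if r.chrom in track.values:
            lo = max(0, r.start)
            hi = min(r.end, track.chrom_length(r.chrom))
            covered = int(np.count_nonzero(track.values[r.chrom][lo:hi])) if lo < hi else 0
        else:
            covered = 0
        name = r.name if r.name is not None else f"{r.chrom}:{r.start}-{r.end}"
        out.append(RegionSignal(name=name, mean_signal=mean, n_covered_bases=covered))
    return out


def trim_extremes(
    values: Sequence[float], lower_frac: float = 0.10, upper_frac: float = 0.10
) -> np.ndarray:
    """Drop the floor(n*lower_frac) smallest and floor(n*upper_frac) largest
    values, preserving the original order of survivors.

    Used on nascent-transcription signal to keep high-signal artifacts from
    dominating metaplot averages.
    """
    if lower_frac < 0 or upper_frac < 0 or lower_frac + upper_frac >= 1:
        raise ValueError("require 0 <= lower_frac + upper_frac < 1")
    v = np.asarray(values, dtype=np.float64)
    n = len(v)
    if n == 0:
        return v
    k_lo = int(np.floor(n * lower_frac))
    k_hi = int(np.floor(n * upper_frac))
    if k_lo + k_hi == 0:
        return v.copy()
    order = np.argsort(v, kind="stable")
    drop = np.concatenate([order[:k_lo], order[n - k_hi :] if k_hi else order[:0]])
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return v[keep]
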