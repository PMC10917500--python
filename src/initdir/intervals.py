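"""Genome annotation and interval arithmetic.

Gene models, region sets, bedtools-style intersect/subtract, and the
extraction of gene-proximal intergenic accessible regions (IARs) —
nuclease-hypersensitive sites lying outside gene bodies within a
configurable distance window (default 100–2000 bp) of a gene.

All internal coordinates are 0-based half-open. GFF3 (1-based closed) and
BED (0-based half-open) conversion is localized in the readers/writers.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence


class AnnotationError(ValueError):
    """Malformed annotation input (carries the offending line number)."""


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval with TSS/TES anchors.

    Coordinates are 0-based half-open.  The TSS is the first transcribed
    base: ``start`` for a plus-strand gene, ``end - 1`` for a minus-strand
    gene; the TES is the opposite terminus.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeLayout:
    """Chromosome sizes plus a collapsed (one interval per gene_id) gene set."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > size:
                raise ValueError(
                    f"gene {g.gene_id} [{g.start},{g.end}) exceeds {g.chrom} length {size}"
                )

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.start, g.end)):
            out.setdefault(g.chrom, []).append(g)
        return out

    def gene_regions(self) -> "RegionSet":
        return RegionSet(
            [Region(g.chrom, g.start, g.end, g.gene_id, g.strand) for g in self.genes],
            provenance="gene bodies",
        )


@dataclass
class RegionSet:
    """An ordered collection of genomic intervals with a provenance label.

    Regions are kept sorted by (chrom, start, end); construction validates
    0 <= start < end.
    """

    regions: list[Region]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean = []
        for r in self.regions:
            r = Region(*r) if not isinstance(r, Region) else r
            if r.start != int(r.start) or r.end != int(r.end):
                raise ValueError(f"non-integer coordinates in {r}")
            if not (0 <= r.start < r.end):
                raise ValueError(f"invalid interval {r}")
            clean.append(r)
        self.regions = sorted(clean, key=lambda r: (r.chrom, r.start, r.end))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out


@dataclass(frozen=True)
class IAR:
    """An intergenic accessible region annotated with its nearest gene.

    ``relative_position`` is with respect to the nearest gene's orientation:
    ``upstream-of-gene`` means the region lies on the gene's 5' side.
    ``distance_to_gene`` is the gap (bp) between the region's closest edge
    and the nearest gene boundary (or TSS when anchored on the TSS).
    """

    chrom: str
    start: int
    end: int
    nearest_gene_id: str
    nearest_gene_strand: str
    relative_position: str
    distance_to_gene: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{i}: expected 'chrom length'")
            if parts[0] in sizes:
                raise AnnotationError(f"{path}:{i}: duplicate chromosome {parts[0]}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(
    path: str | Path,
    format: str | None = None,
    chrom_sizes: str | Path | dict[str, int] | None = None,
    feature_type: str = "gene",
) -> GenomeLayout:
    """Read a gene annotation (GFF3 or BED) into a :class:`GenomeLayout`.

    GFF3 coordinates (1-based closed) are shifted to the internal 0-based
    half-open convention; BED is taken as-is.  Chromosome sizes come from
    ``chrom_sizes`` (path or mapping), from a ``<path>.chrom.sizes`` sidecar
    if present, or are inferred as the maximum gene end per chromosome.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")

    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "gff3":
                    if len(fields) < 8:
                        raise AnnotationError(f"{path}:{i}: too few GFF3 columns")
                    if fields[2] != feature_type:
                        continue
                    chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                    attrs = _parse_gff3_attributes(fields[8]) if len(fields) > 8 else {}
                    gene_id = attrs.get("ID") or attrs.get("gene_id") or f"gene{len(genes)+1}"
                else:
                    if len(fields) < 3:
                        raise AnnotationError(f"{path}:{i}: too few BED columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 else f"gene{len(genes)+1}"
                    strand = fields[5] if len(fields) > 5 else "+"
            except (ValueError, IndexError) as exc:
                if isinstance(exc, AnnotationError):
                    raise
                raise AnnotationError(f"{path}:{i}: malformed line: {exc}") from exc
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{i}: unknown strand {strand!r}")
            if gene_id in seen:
                # collapse isoforms: keep one interval per gene_id (spanning union)
                for j, g in enumerate(genes):
                    if g.gene_id == gene_id:
                        genes[j] = GeneModel(
                            g.chrom, min(g.start, start), max(g.end, end), g.strand, gene_id
                        )
                        break
                continue
            seen.add(gene_id)
            genes.append(GeneModel(chrom, start, end, strand, gene_id))

    if isinstance(chrom_sizes, dict):
        sizes = dict(chrom_sizes)
    elif chrom_sizes is not None:
        sizes = read_chrom_sizes(chrom_sizes)
    else:
        sidecar = path.with_suffix(path.suffix + ".chrom.sizes")
        if sidecar.exists():
            sizes = read_chrom_sizes(sidecar)
        else:
            sizes = {}
            for g in genes:
                sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end)
    return GenomeLayout(chrom_sizes=sizes, genes=genes)


def write_gff3(layout: GenomeLayout, path: str | Path, source: str = "initdir") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in layout.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in sorted(layout.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed(path: str | Path, provenance: str | None = None) -> RegionSet:
    """Read BED3/BED6 into a RegionSet (BED is already 0-based half-open)."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise AnnotationError(f"{path}:{i}: too few BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{i}: malformed line: {exc}") from exc
            name = f[3] if len(f) > 3 else None
            strand = f[5] if len(f) > 5 else None
            if strand is not None and strand not in ("+", "-", "."):
                raise AnnotationError(f"{path}:{i}: unknown strand {strand!r}")
            regions.append(Region(f[0], start, end, name, None if strand == "." else strand))
    return RegionSet(regions, provenance=provenance or str(path))


def write_bed6(regions: Iterable[Region | IAR], path: str | Path) -> None:
    """Write regions (or IARs) as BED6.

    For IARs: name = nearest gene id, score = distance to gene, strand =
    nearest gene strand.
    """
    with open(path, "w") as fh:
        for r in regions:
            if isinstance(r, IAR):
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.nearest_gene_id}\t"
                    f"{r.distance_to_gene}\t{r.nearest_gene_strand}\n"
                )
            else:
                name = r.name if r.name is not None else "."
                strand = r.strand if r.strand is not None else "."
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def _merge(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    """Parts of each region of ``a`` not covered by any region of ``b``.

    Output fragments inherit the source region's name and strand and are
    non-overlapping within each source region.
    """
    b_by_chrom = {c: _merge([(r.start, r.end) for r in rs]) for c, rs in b.by_chrom().items()}
    out: list[Region] = []
    for r in a:
        blockers = b_by_chrom.get(r.chrom, [])
        starts = [s for s, _ in blockers]
        cursor = r.start
        idx = bisect.bisect_right(starts, r.start) - 1
        idx = max(idx, 0)
        pieces: list[tuple[int, int]] = []
        for s, e in blockers[idx:]:
            if e <= cursor:
                continue
            if s >= r.end:
                break
            if s > cursor:
                pieces.append((cursor, min(s, r.end)))
            cursor = max(cursor, e)
            if cursor >= r.end:
                break
        if cursor < r.end:
            pieces.append((cursor, r.end))
        out.extend(Region(r.chrom, s, e, r.name, r.strand) for s, e in pieces if s < e)
    return RegionSet(out, provenance=f"subtract({a.provenance}, {b.provenance})")


def interval_intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Overlapping parts of regions of ``a`` with the union of ``b``."""
    b_by_chrom = {c: _merge([(r.start, r.end) for r in rs]) for c, rs in b.by_chrom().items()}
    out: list[Region] = []
    for r in a:
        blockers = b_by_chrom.get(r.chrom, [])
        starts = [s for s, _ in blockers]
        idx = max(bisect.bisect_right(starts, r.start) - 1, 0)
        for s, e in blockers[idx:]:
            if s >= r.end:
                break
            lo, hi = max(s, r.start), min(e, r.end)
            if lo < hi:
                out.append(Region(r.chrom, lo, hi, r.name, r.strand))
    return RegionSet(out, provenance=f"intersect({a.provenance}, {b.provenance})")


# ---------------------------------------------------------------------------
# IAR extraction
# ---------------------------------------------------------------------------

def _gap_to_interval(s: int, e: int, gs: int, ge: int) -> int:
    """Gap in bp between [s,e) and [gs,ge); 0 if they touch or overlap."""
    if e <= gs:
        return gs - e
    if s >= ge:
        return s - ge
    return 0


def extract_iars(
    layout: GenomeLayout,
    accessible: RegionSet,
    min_dist: int = 100,
    max_dist: int = 2000,
    min_width: int = 50,
    anchor: str = "gene",
) -> list[IAR]:
    """Extract gene-proximal intergenic accessible regions.

    Accessible regions are first clipped against gene bodies
    (:func:`interval_subtract`); fragments narrower than ``min_width`` are
    dropped.  A surviving fragment is an IAR when the gap between its
    closest edge and the nearest gene boundary (``anchor="gene"``) or the
    nearest TSS (``anchor="tss"``) lies in ``[min_dist, max_dist]``.  A
    fragment within range of several genes is counted once, assigned to the
    nearest gene (ties resolve to the leftmost gene by coordinate).
    """
    if not layout.genes:
        raise ValueError("IAR extraction requires a non-empty gene set")
    if anchor not in ("gene", "tss"):
        raise ValueError(f"anchor must be 'gene' or 'tss', got {anchor!r}")

    fragments = interval_subtract(accessible, layout.gene_regions())
    genes_by_chrom = layout.genes_by_chrom()

    iars: list[IAR] = []
    seen: set[tuple[str, int, int]] = set()
    for frag in fragments:
        if frag.end - frag.start < min_width:
            continue
        key = (frag.chrom, frag.start, frag.end)
        if key in seen:
            continue
        genes = genes_by_chrom.get(frag.chrom, [])
        best: tuple[int, int, str, GeneModel] | None = None  # (dist, gstart, gid, gene)
        for g in genes:
            if anchor == "gene":
                d = _gap_to_interval(frag.start, frag.end, g.start, g.end)
            else:
                d = _gap_to_interval(frag.start, frag.end, g.tss, g.tss + 1)
            cand = (d, g.start, g.gene_id, g)
            if best is None or cand[:3] < best[:3]:
                best = cand
        assert best is not None
        dist, _, _, gene = best
        if not (min_dist <= dist <= max_dist):
            continue
        seen.add(key)
        left_of_gene = frag.end <= gene.start if anchor == "gene" else frag.end <= gene.tss + 1
        if gene.strand == "+":
            relpos = "upstream-of-gene" if left_of_gene else "downstream-of-gene"
        else:
            relpos = "downstream-of-gene" if left_of_gene else "upstream-of-gene"
        iars.append(
            IAR(
                chrom=frag.chrom,
                start=frag.start,
                end=frag.end,
                nearest_gene_id=gene.gene_id,
                nearest_gene_strand=gene.strand,
                relative_position=relpos,
                distance_to_gene=dist,
            )
        )
    iars.sort(key=lambda r: (r.chrom, r.start, r.end))
    return iars


def flanks_from_midpoint(
    iar: IAR | Region,
    flank: int = 2000,
    chrom_size: int | None = None,
) -> tuple[Region, Region, bool]:
    """Upstream/downstream flank intervals around an interval midpoint.

    Upstream = [midpoint - flank, midpoint), downstream = [midpoint,
    midpoint + flank), both in genomic coordinates and clipped at
    chromosome bounds.  Returns (upstream, downstream, clipped_flag).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    mid = (iar.start + iar.end) // 2
    up_start, up_end = mid - flank, mid
    down_start, down_end = mid, mid + flank
    clipped = False
    if up_start < 0:
        up_start, clipped = 0, True
    if chrom_size is not None and down_end > chrom_size:
        down_end, clipped = chrom_size, True
    name = iar.name if isinstance(iar, IAR) else (iar.name or f"{iar.chrom}:{iar.start}-{iar.end}")
    up = Region(iar.chrom, up_start, up_end, f"{name}|up")
    down = Region(iar.chrom, down_start, down_end, f"{name}|down")
    return up, down, clipped
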