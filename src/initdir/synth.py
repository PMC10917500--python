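"""Synthetic epigenome generator.

Simulates, directly at the coverage level (no reads, no sequence), the
statistical structure the directionality analysis assumes:

* gene models on both strands with >= 4 kb spacing and a nucleosome-
  depleted accessibility peak just upstream of each TSS;
* intergenic cis-regulatory elements (CREs) placed 100-2000 bp from a
  gene (so they survive IAR extraction) plus decoy accessible sites
  placed far from any gene (which must not survive);
* strand-specific nascent transcription with controllable uni- vs
  bidirectional initiation: sense coverage decaying 5'->3' over gene
  bodies, short (~500 bp) non-elongating divergent/eRNA windows;
* transcription-coupled histone-PTM flank signal (H3K4me3 proximal,
  H3K4me1 distal, H3K27ac on active sides, H3K27me3 on inactive
  elements, H2A.Z on transcribed flanks, an H3 nucleosome baseline with
  an NDR dip) and an accessibility peak at every accessible site;
* Poisson count noise per bin (negative-binomial overdispersion
  optional), or exact expected values in noiseless mode.

Tracks are assumed to represent MAPQ-filtered coverage; read filtering
itself is upstream of this model.  All outputs are reproducible
bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    IAR,
    GeneModel,
    GenomeLayout,
    Region,
    RegionSet,
    write_bed6,
    write_chrom_sizes,
    write_gff3,
)
from .signal import CoverageTrack

DEFAULT_MARKS: dict[str, dict] = {
    # offsets/widths in bp from the element anchor; amplitude in expected
    # reads per base at the bump center
    "H3K4me3": {"offset": 300, "width": 150, "amplitude": 0.6, "where": "transcribed"},
    "H3K4me1": {"offset": 800, "width": 300, "amplitude": 0.5, "where": "transcribed"},
    "H3K27ac": {"offset": 250, "width": 200, "amplitude": 0.5, "where": "transcribed"},
    "H3K27me3": {"offset": 0, "width": 800, "amplitude": 0.4, "where": "inactive"},
    "H2A.Z": {"offset": 200, "width": 150, "amplitude": 0.4, "where": "transcribed"},
    "accessibility": {"offset": 0, "width": 80, "amplitude": 1.0, "where": "center"},
    "H3": {"offset": 0, "width": 100, "amplitude": 0.25, "where": "ndr_dip", "baseline": 0.3},
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic epigenome.

    Rates are expected reads per base; noise is applied per ``bin_size``
    bp bin.  ``divergent_strength`` is the ratio of antisense to sense
    initiation at bidirectional TSSs.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 200
    gene_length_log_mean: float = 7.31  # log-normal, median ~1500 bp
    gene_length_log_sd: float = 0.45
    gene_length_min: int = 400
    min_gene_spacing: int = 4000
    n_cres: int = 150
    decoy_fraction: float = 0.2
    fraction_bidirectional_tss: float = 0.15
    fraction_bidirectional_cre: float = 0.30
    fraction_inactive_cre: float = 0.20
    fraction_unidirectional_minus: float = 0.5
    divergent_strength: float = 0.8
    antisense_window: int = 500
    erna_window: int = 500
    gene_rate: float = 0.5
    gene_decay: float = 3000.0
    cre_rate: float = 0.4
    background_rate: float = 0.02
    bin_size: int = 10
    noise: bool = True
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    ndr_width: int = 200
    ndr_offset: int = 50  # gap between NDR edge and the TSS (< IAR min_dist)
    cre_width_min: int = 200
    cre_width_max: int = 400
    cre_min_dist: int = 1200
    cre_max_dist: int = 1800
    decoy_min_dist: int = 2500
    marks: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKS.items()})

    def __post_init__(self) -> None:
        for name in (
            "decoy_fraction",
            "fraction_bidirectional_tss",
            "fraction_bidirectional_cre",
            "fraction_inactive_cre",
            "fraction_unidirectional_minus",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("chrom_length", "n_chromosomes", "bin_size", "gene_length_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class Element:
    """One simulated element with its directionality label and class."""

    element_id: str
    kind: str  # gene | cre | decoy
    chrom: str
    start: int
    end: int
    strand: str | None
    label: str  # unidirectional-plus | unidirectional-minus | bidirectional | inactive
    cls: str  # unidirectional | bidirectional | inactive | decoy

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GroundTruth:
    """Per-element directionality labels and clustering classes."""

    elements: list[Element]

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate element ids in ground truth")

    def by_kind(self, kind: str) -> list[Element]:
        return [e for e in self.elements if e.kind == kind]

    def match_iars(self, iars: list[IAR]) -> dict[str, Element]:
        """Map IAR name -> overlapping CRE/decoy element (by interval overlap)."""
        out = {}
        for iar in iars:
            for e in self.elements:
                if e.kind == "gene":
                    continue
                if e.chrom == iar.chrom and iar.start < e.end and e.start < iar.end:
                    out[iar.name] = e
                    break
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "element_id": e.element_id,
                    "kind": e.kind,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "strand": e.strand or ".",
                    "label": e.label,
                    "class": e.cls,
                }
                for e in self.elements
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                Element(
                    element_id=str(r["element_id"]),
                    kind=str(r["kind"]),
                    chrom=str(r["chrom"]),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    strand=None if r["strand"] == "." else str(r["strand"]),
                    label=str(r["label"]),
                    cls=str(r["class"]),
                )
                for _, r in df.iterrows()
            ]
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Genome / element placement
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeLayout, RegionSet, GroundTruth]:
    """Place genes, promoter NDRs, proximal CREs and distal decoys.

    Genes are placed uniformly without overlap with at least
    ``min_gene_spacing`` bp between neighbours; CREs go 100-2000 bp from a
    gene boundary (placement range ``cre_min_dist``-``cre_max_dist``);
    decoys at least ``decoy_min_dist`` bp from every gene.
    """
    if config.n_genes == 0:
        raise ValueError("simulation requires at least one gene (IARs are undefined without genes)")
    rng = _rng(config, 0)
    edge_margin = 5000

    chrom_sizes = {f"chr{i+1}": config.chrom_length for i in range(config.n_chromosomes)}
    genes: list[GeneModel] = []
    elements: list[Element] = []
    accessible: list[Region] = []

    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1
    cres_per_chrom = np.full(config.n_chromosomes, config.n_cres // config.n_chromosomes)
    cres_per_chrom[: config.n_cres % config.n_chromosomes] += 1
    n_decoys = int(round(config.n_cres * config.decoy_fraction))
    decoys_per_chrom = np.full(config.n_chromosomes, n_decoys // config.n_chromosomes)
    decoys_per_chrom[: n_decoys % config.n_chromosomes] += 1

    gene_counter = 0
    cre_counter = 0
    decoy_counter = 0
    for ci, (chrom, size) in enumerate(chrom_sizes.items()):
        ng = int(genes_per_chrom[ci])
        lengths = np.exp(
            rng.normal(config.gene_length_log_mean, config.gene_length_log_sd, ng)
        )
        lengths = np.maximum(lengths.astype(int), config.gene_length_min)
        avail = size - 2 * edge_margin
        slack = avail - int(lengths.sum()) - (ng + 1) * config.min_gene_spacing
        if slack < 0:
            raise ValueError(
                f"cannot pack {ng} genes (total {int(lengths.sum())} bp) into {chrom} "
                f"({size} bp) with {config.min_gene_spacing} bp spacing"
            )
        gaps = config.min_gene_spacing + np.floor(
            rng.dirichlet(np.ones(ng + 1)) * slack
        ).astype(int)
        pos = edge_margin
        chrom_genes: list[GeneModel] = []
        for i in range(ng):
            pos += int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gene_counter + 1:04d}"
            gene_counter += 1
            g = GeneModel(chrom, start, end, strand, gid)
            chrom_genes.append(g)
            pos = end
            bidir = rng.random() < config.fraction_bidirectional_tss
            label = "bidirectional" if bidir else (
                "unidirectional-plus" if strand == "+" else "unidirectional-minus"
            )
            elements.append(
                Element(gid, "gene", chrom, start, end, strand, label,
                        "bidirectional" if bidir else "unidirectional")
            )
            # promoter NDR just upstream of the TSS, closer than the IAR
            # distance floor so it is excluded from IAR extraction
            lo = config.ndr_offset
            hi = config.ndr_offset + config.ndr_width
            if strand == "+":
                ndr = Region(chrom, start - hi, start - lo, f"{gid}_ndr")
            else:
                ndr = Region(chrom, end + lo, end + hi, f"{gid}_ndr")
            accessible.append(ndr)
        genes.extend(chrom_genes)

        occupied = [(r.start, r.end) for r in accessible if r.chrom == chrom]
        occupied += [(g.start, g.end) for g in chrom_genes]

        def free(s: int, e: int, pad: int = 100) -> bool:
            return all(e + pad <= os or oe + pad <= s for os, oe in occupied)

        def nearest_gene_gap(s: int, e: int) -> int:
            best = size
            for g in chrom_genes:
                if e <= g.start:
                    best = min(best, g.start - e)
                elif s >= g.end:
                    best = min(best, s - g.end)
                else:
                    return 0
            return best

        # proximal CREs
        for _ in range(int(cres_per_chrom[ci])):
            placed = False
            for _attempt in range(500):
                g = chrom_genes[rng.integers(len(chrom_genes))]
                side = -1 if rng.random() < 0.5 else 1
                d = int(rng.integers(config.cre_min_dist, config.cre_max_dist + 1))
                w = int(rng.integers(config.cre_width_min, config.cre_width_max + 1))
                if side < 0:
                    s, e = g.start - d - w, g.start - d
                else:
                    s, e = g.end + d, g.end + d + w
                if s < 0 or e > size or not free(s, e):
                    continue
                if nearest_gene_gap(s, e) != d:
                    continue
                u = rng.random()
                if u < config.fraction_bidirectional_cre:
                    label, cls = "bidirectional", "bidirectional"
                elif u < config.fraction_bidirectional_cre + config.fraction_inactive_cre:
                    label, cls = "inactive", "inactive"
                else:
                    minus = rng.random() < config.fraction_unidirectional_minus
                    label = "unidirectional-minus" if minus else "unidirectional-plus"
                    cls = "unidirectional"
                cid = f"cre{cre_counter + 1:04d}"
                cre_counter += 1
                elements.append(Element(cid, "cre", chrom, s, e, None, label, cls))
                accessible.append(Region(chrom, s, e, cid))
                occupied.append((s, e))
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place a CRE on {chrom}; genome too crowded")

        # decoys: far from every gene, must NOT survive IAR extraction
        for _ in range(int(decoys_per_chrom[ci])):
            placed = False
            for _attempt in range(2000):
                w = int(rng.integers(config.cre_width_min, config.cre_width_max + 1))
                s = int(rng.integers(0, size - w))
                e = s + w
                if not free(s, e):
                    continue
                if nearest_gene_gap(s, e) < config.decoy_min_dist:
                    continue
                did = f"decoy{decoy_counter + 1:04d}"
                decoy_counter += 1
                elements.append(Element(did, "decoy", chrom, s, e, None, "inactive", "decoy"))
                accessible.append(Region(chrom, s, e, did))
                occupied.append((s, e))
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place a decoy on {chrom}")

    layout = GenomeLayout(chrom_sizes=chrom_sizes, genes=genes)
    regions = RegionSet(accessible, provenance="synthetic accessible sites")
    truth = GroundTruth(elements)
    return layout, regions, truth


# ---------------------------------------------------------------------------
# Coverage synthesis
# ---------------------------------------------------------------------------

def _sample_track(
    rates: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    strand: str,
    label: str,
) -> CoverageTrack:
    """Per-bin count noise on expected per-base rates, expanded per base.

    Each ``bin_size`` bp bin draws one count with mean = sum of per-base
    rates in the bin; all bases of a bin carry the bin's count.  In
    noiseless mode the expected bin count is used directly.
    """
    b = config.bin_size
    values = {}
    for chrom, rate in rates.items():
        n = len(rate)
        n_bins = (n + b - 1) // b
        padded = np.zeros(n_bins * b)
        padded[:n] = rate
        lam = padded.reshape(n_bins, b).sum(axis=1)
        if not config.noise:
            counts = lam
        elif config.overdispersion is not None:
            r = config.overdispersion
            p = r / (r + lam)
            counts = rng.negative_binomial(r, p).astype(np.float64)
        else:
            counts = rng.poisson(lam).astype(np.float64)
        values[chrom] = np.repeat(counts, b)[:n]
    return CoverageTrack(values, strand=strand, label=label, bin_size=b)


def _zero_rates(layout: GenomeLayout, base: float = 0.0) -> dict[str, np.ndarray]:
    return {c: np.full(n, base, dtype=np.float64) for c, n in layout.chrom_sizes.items()}


def _add_flat(rates: dict[str, np.ndarray], chrom: str, s: int, e: int, amp: float) -> None:
    n = len(rates[chrom])
    lo, hi = max(0, s), min(e, n)
    if lo < hi:
        rates[chrom][lo:hi] += amp


def _add_bump(rates: dict[str, np.ndarray], chrom: str, center: int, width: float, amp: float) -> None:
    n = len(rates[chrom])
    lo = max(0, int(center - 4 * width))
    hi = min(n, int(center + 4 * width) + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi)
    rates[chrom][lo:hi] += amp * np.exp(-0.5 * ((x - center) / width) ** 2)


def _element_sides(e: Element) -> list[int]:
    """Transcribed sides in genomic coordinates: -1 = left, +1 = right."""
    if e.kind == "gene":
        body = 1 if e.strand == "+" else -1
        return [body, -body] if e.label == "bidirectional" else [body]
    if e.label == "unidirectional-plus":
        return [1]
    if e.label == "unidirectional-minus":
        return [-1]
    if e.label == "bidirectional":
        return [-1, 1]
    return []


def _element_anchor(e: Element, config: SimulationConfig) -> int:
    """PTM/accessibility anchor: the accessible-site center."""
    if e.kind == "gene":
        off = config.ndr_offset + config.ndr_width // 2
        return e.start - off if e.strand == "+" else e.end + off
    return e.midpoint


def simulate_nascent(
    layout: GenomeLayout,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Strand-separated nascent-transcription coverage (plus, minus).

    Sense coverage decays exponentially 5'->3' along gene bodies; at
    bidirectional TSSs a short antisense window upstream carries
    ``divergent_strength`` times the sense initiation rate; CRE eRNAs are
    short flat windows on the transcribed side(s).  A uniform background
    rate applies on both strands.
    """
    plus = _zero_rates(layout)
    minus = _zero_rates(layout)
    for r in (plus, minus):
        for c in r:
            r[c] += config.background_rate

    gene_by_id = {g.gene_id: g for g in layout.genes}
    for e in truth.elements:
        if e.kind == "gene":
            g = gene_by_id[e.element_id]
            x = np.arange(g.start, g.end)
            dist = x - g.start if g.strand == "+" else g.end - 1 - x
            decay = config.gene_rate * np.exp(-dist / config.gene_decay)
            target = plus if g.strand == "+" else minus
            target[g.chrom][g.start : g.end] += decay
            if e.label == "bidirectional":
                amp = config.divergent_strength * config.gene_rate
                aw = config.antisense_window
                if g.strand == "+":
                    _add_flat(minus, g.chrom, g.tss - aw, g.tss, amp)
                else:
                    _add_flat(plus, g.chrom, g.tss + 1, g.tss + 1 + aw, amp)
        elif e.kind in ("cre", "decoy"):
            mid = e.midpoint
            ew = config.erna_window
            for side in _element_sides(e):
                if side > 0:
                    _add_flat(plus, e.chrom, mid, mid + ew, config.cre_rate)
                else:
                    _add_flat(minus, e.chrom, mid - ew, mid, config.cre_rate)

    rng = _rng(config, 1)
    plus_track = _sample_track(plus, config, rng, "+", "nascent_plus")
    minus_track = _sample_track(minus, config, rng, "-", "nascent_minus")
    return plus_track, minus_track


def simulate_ptm_tracks(
    layout: GenomeLayout,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, CoverageTrack]:
    """Histone-PTM / accessibility / nucleosome coverage tracks.

    Marks with ``where="transcribed"`` get a Gaussian bump on each
    transcribed side of each element (both sides iff bidirectional) at
    the configured offset/width; ``"inactive"`` marks go on inactive
    elements; ``"center"`` marks peak at every accessible-site anchor;
    ``"ndr_dip"`` is a uniform baseline minus a bump at each anchor.
    """
    tracks = {}
    rng = _rng(config, 2)
    for mark, spec in config.marks.items():
        where = spec["where"]
        baseline = spec.get("baseline", 0.0)
        rates = _zero_rates(layout, base=baseline + config.background_rate / 2)
        for e in truth.elements:
            anchor = _element_anchor(e, config)
            if where == "transcribed":
                for side in _element_sides(e):
                    _add_bump(
                        rates, e.chrom, anchor + side * spec["offset"], spec["width"], spec["amplitude"]
                    )
            elif where == "inactive":
                if e.label == "inactive":
                    _add_bump(rates, e.chrom, anchor, spec["width"], spec["amplitude"])
            elif where == "center":
                _add_bump(rates, e.chrom, anchor, spec["width"], spec["amplitude"])
            elif where == "ndr_dip":
                _add_bump(rates, e.chrom, anchor, spec["width"], -spec["amplitude"])
            else:
                raise ValueError(f"unknown mark placement {where!r}")
        for c in rates:
            np.clip(rates[c], 0.0, None, out=rates[c])
        tracks[mark] = _sample_track(rates, config, rng, "unstranded", mark)
    return tracks


# ---------------------------------------------------------------------------
# One-call simulation with file outputs
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    layout: GenomeLayout
    accessible: RegionSet
    truth: GroundTruth
    tracks: dict[str, CoverageTrack]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write GFF3 + chrom.sizes + BEDs + one bedGraph per track."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_gff3(self.layout, outdir / "genes.gff3")
        paths["annotation"] = str(outdir / "genes.gff3")
        write_chrom_sizes(self.layout.chrom_sizes, outdir / "genome.chrom.sizes")
        paths["chrom_sizes"] = str(outdir / "genome.chrom.sizes")
        write_bed6(self.accessible, outdir / "accessible.bed")
        paths["accessible"] = str(outdir / "accessible.bed")
        self.truth.write_tsv(outdir / "truth.tsv")
        paths["truth"] = str(outdir / "truth.tsv")
        self.config.to_yaml(outdir / "sim_config.yaml")
        tracks_dir = outdir / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for name, track in self.tracks.items():
            p = tracks_dir / f"{name.replace('.', '')}.bedgraph"
            track.write_bedgraph(p)
            paths[f"track:{name}"] = str(p)
        return paths


def simulate_all(config: SimulationConfig) -> SimulationResult:
    layout, accessible, truth = simulate_genome(config)
    plus, minus = simulate_nascent(layout, truth, config)
    tracks = {"nascent_plus": plus, "nascent_minus": minus}
    tracks.update(simulate_ptm_tracks(layout, truth, config))
    return SimulationResult(
        config=config, layout=layout, accessible=accessible, truth=truth, tracks=tracks
    )
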