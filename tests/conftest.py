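import numpy as np
import pytest

from initdir.intervals import GeneModel, GenomeLayout, Region, RegionSet
from initdir.synth import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small (400 kb) synthetic epigenome shared across tests."""
    cfg = SimulationConfig(seed=11, chrom_length=400_000, n_genes=40, n_cres=30)
    return simulate_all(cfg)


@pytest.fixture
def toy_layout():
    """Hand-built 3-gene layout with accessible regions spanning every
    IAR-extraction case, plus the hand-derived expected IAR set.

    Cases: inside a gene body, overlapping a gene edge (clipped, then too
    close), in-window on either side of +/- genes, beyond 2 kb, closer
    than 100 bp, and narrower than the minimum width.
    """
    layout = GenomeLayout(
        chrom_sizes={"c": 60_000},
        genes=[
            GeneModel("c", 5_000, 8_000, "+", "gA"),
            GeneModel("c", 20_000, 23_000, "-", "gB"),
            GeneModel("c", 40_000, 46_000, "+", "gC"),
        ],
    )
    accessible = RegionSet(
        [
            Region("c", 6_000, 6_200, "inside_gene"),
            Region("c", 4_950, 5_050, "overlaps_edge"),
            Region("c", 3_500, 3_700, "upstream_in_window"),
            Region("c", 8_150, 8_400, "downstream_in_window"),
            Region("c", 30_000, 30_200, "too_far"),
            Region("c", 18_500, 18_600, "near_minus_gene"),
            Region("c", 23_050, 23_120, "too_close"),
            Region("c", 38_500, 38_530, "too_narrow"),
        ],
        provenance="toy accessible",
    )
    # (start, end, nearest_gene, strand, relative_position, distance)
    expected = [
        (3_500, 3_700, "gA", "+", "upstream-of-gene", 1_300),
        (8_150, 8_400, "gA", "+", "downstream-of-gene", 150),
        (18_500, 18_600, "gB", "-", "downstream-of-gene", 1_400),
    ]
    return layout, accessible, expected


def bitmap_subtract(a, b, genome_len):
    """Per-base membership oracle for interval subtraction."""
    cov_b = np.zeros(genome_len, dtype=bool)
    for r in b:
        cov_b[r.start : r.end] = True
    out = []
    for r in a:
        keep = ~cov_b[r.start : r.end]
        out.extend(_runs(keep, r.start))
    return sorted(out)


def bitmap_intersect(a, b, genome_len):
    cov_b = np.zeros(genome_len, dtype=bool)
    for r in b:
        cov_b[r.start : r.end] = True
    out = []
    for r in a:
        keep = cov_b[r.start : r.end]
        out.extend(_runs(keep, r.start))
    return sorted(out)


def _runs(mask, offset):
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((offset + start, offset + i))
            start = None
    if start is not None:
        runs.append((offset + start, offset + len(mask)))
    return runs


def random_region_set(rng, n, genome_len, max_width=400, name="rs"):
    regions = []
    for _ in range(n):
        w = int(rng.integers(1, max_width))
        s = int(rng.integers(0, genome_len - w))
        regions.append(Region("c", s, s + w))
    return RegionSet(regions, provenance=name)
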