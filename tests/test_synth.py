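import numpy as np
import pytest

from initdir.intervals import extract_iars
from initdir.synth import (
    SimulationConfig,
    simulate_all,
    simulate_genome,
    simulate_nascent,
    simulate_ptm_tracks,
)


SMALL = dict(chrom_length=400_000, n_genes=40, n_cres=30)


class TestConfig:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="fraction_bidirectional_cre"):
            SimulationConfig(fraction_bidirectional_cre=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_genes=17, cre_rate=0.7)
        p = tmp_path / "c.yaml"
        cfg.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == cfg


class TestGenomePlacement:
    def test_no_genes_is_an_error(self):
        with pytest.raises(ValueError, match="gene"):
            simulate_genome(SimulationConfig(seed=0, n_genes=0, n_cres=5))

    def test_infeasible_packing_is_an_error(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_genome(SimulationConfig(seed=0, chrom_length=100_000, n_genes=50, n_cres=0))

    def test_spacing_and_bounds_constraints_hold(self):
        cfg = SimulationConfig(seed=2, chrom_length=2_000_000, n_genes=100, n_cres=50)
        layout, accessible, truth = simulate_genome(cfg)
        by_chrom = layout.genes_by_chrom()
        for genes in by_chrom.values():
            for g1, g2 in zip(genes, genes[1:]):
                assert g2.start - g1.end >= cfg.min_gene_spacing
        for r in accessible:
            assert 0 <= r.start < r.end <= layout.chrom_sizes[r.chrom]

    def test_cres_survive_extraction_and_decoys_never_do(self, small_sim):
        iars = extract_iars(small_sim.layout, small_sim.accessible)
        matched = small_sim.truth.match_iars(iars)
        assert len(matched) == len(iars)
        kinds = {e.kind for e in matched.values()}
        assert kinds == {"cre"}
        n_cres = len(small_sim.truth.by_kind("cre"))
        assert len(iars) == n_cres

    def test_same_seed_reproduces_identical_genome(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a[0].genes == b[0].genes
        assert list(a[1]) == list(b[1])
        assert a[2].to_frame().equals(b[2].to_frame())


class TestNascent:
    def test_no_bidirectional_tss_means_background_antisense_upstream(self):
        cfg = SimulationConfig(seed=6, fraction_bidirectional_tss=0.0,
                               fraction_bidirectional_cre=0.0, noise=False, **SMALL)
        layout, _, truth = simulate_genome(cfg)
        plus, minus = simulate_nascent(layout, truth, cfg)
        anti = {"+": minus, "-": plus}
        for g in layout.genes:
            track = anti[g.strand]
            if g.strand == "+":
                m = track.mean(g.chrom, g.tss - 500, g.tss)
            else:
                m = track.mean(g.chrom, g.tss + 1, g.tss + 501)
            # expected value equals the per-bin background in noiseless mode
            assert m == pytest.approx(cfg.background_rate * cfg.bin_size, rel=0.3)

    def test_divergent_strength_one_gives_symmetric_bidirectional_cre(self):
        cfg = SimulationConfig(seed=7, fraction_bidirectional_cre=1.0,
                               fraction_inactive_cre=0.0, noise=False, **SMALL)
        layout, _, truth = simulate_genome(cfg)
        plus, minus = simulate_nascent(layout, truth, cfg)
        for e in truth.by_kind("cre"):
            mid = e.midpoint
            down = plus.mean(e.chrom, mid, mid + cfg.erna_window)
            up = minus.mean(e.chrom, mid - cfg.erna_window, mid)
            assert down == pytest.approx(up, rel=1e-6)

    def test_doubling_rate_doubles_expected_coverage(self):
        base = SimulationConfig(seed=8, noise=False, **SMALL)
        doubled = SimulationConfig(seed=8, noise=False, cre_rate=0.8, **SMALL)
        layout, _, truth = simulate_genome(base)
        p1, m1 = simulate_nascent(layout, truth, base)
        p2, m2 = simulate_nascent(layout, truth, doubled)
        for e in truth.by_kind("cre"):
            if e.label != "unidirectional-plus":
                continue
            mid = e.midpoint
            s1 = p1.mean(e.chrom, mid, mid + 500) - base.background_rate * base.bin_size
            s2 = p2.mean(e.chrom, mid, mid + 500) - base.background_rate * base.bin_size
            assert s2 == pytest.approx(2 * s1, rel=1e-9)

    def test_poisson_noise_has_matching_mean(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        layout, _, truth = simulate_genome(cfg)
        plus, _ = simulate_nascent(layout, truth, cfg)
        cfg_nn = SimulationConfig(seed=9, noise=False, **SMALL)
        plus_nn, _ = simulate_nascent(layout, truth, cfg_nn)
        genes = [g for g in layout.genes if g.strand == "+"]
        got = np.mean([plus.mean(g.chrom, g.start, g.end) for g in genes])
        expected = np.mean([plus_nn.mean(g.chrom, g.start, g.end) for g in genes])
        assert got == pytest.approx(expected, rel=0.05)


def _isolated_cres(truth, min_gap=2_500):
    """CREs with no other simulated element within min_gap bp, so side
    windows reflect only the element's own signal."""
    def gap(a, b):
        return max(b.start - a.end, a.start - b.end)

    out = []
    for e in truth.by_kind("cre"):
        others = [o for o in truth.elements
                  if o.element_id != e.element_id and o.chrom == e.chrom]
        if any(o.kind != "gene" and gap(e, o) < min_gap for o in others):
            continue
        if any(o.kind == "gene" and gap(e, o) < 900 for o in others):
            continue
        out.append(e)
    return out


@pytest.fixture(scope="module")
def noiseless():
    cfg = SimulationConfig(seed=10, noise=False, **SMALL)
    layout, _, truth = simulate_genome(cfg)
    return cfg, layout, truth, simulate_ptm_tracks(layout, truth, cfg)


class TestPtmTracks:
    def test_unidirectional_cre_has_one_sided_k4me3(self, noiseless):
        cfg, layout, truth, tracks = noiseless
        k4 = tracks["H3K4me3"]
        off, width = cfg.marks["H3K4me3"]["offset"], cfg.marks["H3K4me3"]["width"]
        checked = 0
        for e in _isolated_cres(truth):
            if not e.label.startswith("unidirectional"):
                continue
            mid = e.midpoint
            right = k4.mean(e.chrom, mid + off - width, mid + off + width)
            left = k4.mean(e.chrom, mid - off - width, mid - off + width)
            ratio = (right / left) if e.label.endswith("plus") else (left / right)
            assert ratio > 4
            checked += 1
        assert checked >= 3

    def test_inactive_cre_has_k27me3_but_no_k4_above_background(self, noiseless):
        cfg, layout, truth, tracks = noiseless
        bg = (cfg.background_rate / 2) * cfg.bin_size
        checked = 0
        for e in _isolated_cres(truth):
            if e.label != "inactive":
                continue
            mid = e.midpoint
            k27 = tracks["H3K27me3"].mean(e.chrom, mid - 400, mid + 400)
            k4 = tracks["H3K4me3"].mean(e.chrom, mid - 600, mid + 600)
            assert k27 > 5 * bg
            assert k4 == pytest.approx(bg, rel=0.05)
            checked += 1
        assert checked >= 1

    def test_accessibility_peaks_at_every_accessible_site(self, noiseless):
        cfg, layout, truth, tracks = noiseless
        acc = tracks["accessibility"]
        checked = 0
        for e in _isolated_cres(truth):
            center = acc.mean(e.chrom, e.midpoint - 50, e.midpoint + 50)
            away = acc.mean(e.chrom, e.midpoint + 500, e.midpoint + 600)
            assert center > 3 * max(away, 1e-9)
            checked += 1
        assert checked >= 3

    def test_h3_is_depleted_in_the_ndr(self, noiseless):
        cfg, layout, truth, tracks = noiseless
        h3 = tracks["H3"]
        g = layout.genes[0]
        anchor = (g.start - cfg.ndr_offset - cfg.ndr_width // 2 if g.strand == "+"
                  else g.end + cfg.ndr_offset + cfg.ndr_width // 2)
        dip = h3.mean(g.chrom, anchor - 50, anchor + 50)
        # baseline reference inside the gene body, clear of the NDR dip
        flat = h3.mean(g.chrom, g.start + 500, g.start + 700)
        assert dip < 0.5 * flat


class TestDeterminismAndOutputs:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=12, **SMALL)
        a = simulate_all(cfg).write(tmp_path / "a")
        b = simulate_all(cfg).write(tmp_path / "b")
        assert a.keys() == b.keys()
        from pathlib import Path

        for key in a:
            assert Path(a[key]).read_bytes() == Path(b[key]).read_bytes(), key

    def test_written_outputs_reload_consistently(self, tmp_path, small_sim):
        paths = small_sim.write(tmp_path / "out")
        from initdir.intervals import read_annotation, read_bed, read_chrom_sizes
        from initdir.signal import load_track

        sizes = read_chrom_sizes(paths["chrom_sizes"])
        layout = read_annotation(paths["annotation"], chrom_sizes=sizes)
        assert sorted(g.gene_id for g in layout.genes) == sorted(
            g.gene_id for g in small_sim.layout.genes
        )
        acc = read_bed(paths["accessible"])
        assert len(acc) == len(small_sim.accessible)
        track = load_track(paths["track:nascent_plus"], chrom_sizes=sizes)
        orig = small_sim.tracks["nascent_plus"]
        np.testing.assert_allclose(track.values["chr1"], orig.values["chr1"])

    def test_negative_binomial_noise_mode_runs(self):
        cfg = SimulationConfig(seed=13, overdispersion=5.0, **SMALL)
        res = simulate_all(cfg)
        assert all(np.isfinite(t.values["chr1"]).all() for t in res.tracks.values())
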