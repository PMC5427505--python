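"""Founder panel generation, preprocessing, and genotype I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gssim
from gssim.founders import (MISSING, FounderPanel, GeneticMap, beta_maf,
                            generate_founder_panel, load_genotype_matrix,
                            preprocess_panel, uniform_maf,
                            write_genotype_matrix)


class TestGeneticMap:
    def test_sorts_and_measures(self):
        gmap = GeneticMap(["a", "b", "c", "d"], [2, 1, 1, 2],
                          [5.0, 10.0, 0.0, 1.0])
        assert list(gmap.chromosome) == [1, 1, 2, 2]
        assert list(gmap.position_cM) == [0.0, 10.0, 1.0, 5.0]
        assert gmap.total_length() == pytest.approx(14.0)

    def test_rejects_negative_positions(self):
        with pytest.raises(ValueError):
            GeneticMap(["a"], [1], [-1.0])


class TestGenerate:
    def test_single_line_is_inbred(self):
        panel = generate_founder_panel(n_lines=1, n_loci=20,
                                       n_chromosomes=2, total_map_cM=100,
                                       seed=0)
        assert panel.n_lines == 1
        assert np.array_equal(panel.haplotypes[0, 0], panel.haplotypes[0, 1])

    def test_default_dimensions_match_study_conditions(self, default_panel):
        assert default_panel.n_lines == 764
        assert default_panel.n_loci == 1590
        assert default_panel.gmap.total_length() == pytest.approx(1137.0)
        assert len(np.unique(default_panel.gmap.chromosome)) == 7
        assert default_panel.is_homozygous()
        assert not default_panel.has_missing()
        # markers emulate a segregating SNP array: all polymorphic
        freq = default_panel.allele2_frequency()
        assert np.all((freq > 0) & (freq < 1))
        assert not default_panel.gmap.has_duplicate_positions()

    def test_seed_reproducibility(self):
        a = generate_founder_panel(n_lines=30, n_loci=50, seed=7)
        b = generate_founder_panel(n_lines=30, n_loci=50, seed=7)
        c = generate_founder_panel(n_lines=30, n_loci=50, seed=8)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.gmap.position_cM, b.gmap.position_cM)
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def test_realized_maf_matches_spectrum(self):
        # large panel, no divergence: realized MAF should be a sample from
        # the requested spectrum (compare quantiles to direct draws)
        panel = generate_founder_panel(
            n_lines=2000, n_loci=800, maf_spectrum=uniform_maf(0.05, 0.5),
            divergence=0.0, seed=3)
        f = panel.allele2_frequency()
        maf = np.minimum(f, 1 - f)
        direct = uniform_maf(0.05, 0.5)(np.random.default_rng(4), 200_000)
        qs = np.linspace(0.05, 0.95, 10)
        assert np.allclose(np.quantile(maf, qs), np.quantile(direct, qs),
                           atol=0.03)

    def test_divergence_is_monotone(self):
        gaps = []
        for div in (0.0, 0.15, 0.4):
            panel = generate_founder_panel(n_lines=400, n_loci=400, seed=5,
                                           divergence=div)
            d = panel.dosage()
            grp = panel.program == panel.program[0]
            p1 = d[grp].mean(axis=0) / 2
            p2 = d[~grp].mean(axis=0) / 2
            gaps.append(np.abs(p1 - p2).mean())
        assert gaps[0] < gaps[1] < gaps[2]

    def test_nearby_loci_are_in_ld(self, default_panel):
        # the generator exists to provide QTL-marker LD: mean r^2 between
        # adjacent markers must clearly exceed the unlinked background
        d = default_panel.dosage().astype(float)
        d = d - d.mean(axis=0)
        sd = d.std(axis=0)
        d /= sd
        gmap = default_panel.gmap
        near, far = [], []
        for _, sl, pos in gmap.chrom_slices():
            block = d[:, sl]
            r_adj = (block[:, :-1] * block[:, 1:]).mean(axis=0)
            close = np.diff(pos) < 2.0
            near.extend((r_adj[close] ** 2).tolist())
        other = d[:, [10, 400, 800, 1200, 1580]]
        rr = np.corrcoef(other.T)
        far = (rr[np.triu_indices(5, 1)] ** 2).tolist()
        assert np.mean(near) > 0.08
        assert np.mean(near) > 5 * np.mean(far)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_founder_panel(n_lines=0)
        with pytest.raises(ValueError):
            generate_founder_panel(divergence=1.5)
        with pytest.raises(ValueError):
            generate_founder_panel(total_map_cM=-1)


def _panel_from_codes(codes, positions=None, chroms=None):
    """Build a raw panel from genotype codes 0/1/2 (−9 = missing)."""
    codes = np.asarray(codes)
    n, m = codes.shape
    haps = np.empty((n, 2, m), dtype=np.int8)
    for (i, j), v in np.ndenumerate(codes):
        haps[i, :, j] = {0: (0, 0), 1: (0, 1), 2: (1, 1),
                         -9: (MISSING, MISSING)}[int(v)]
    gmap = GeneticMap([f"m{j}" for j in range(m)],
                      chroms if chroms is not None else np.ones(m, int),
                      positions if positions is not None else np.arange(m, dtype=float))
    return FounderPanel([f"L{i}" for i in range(n)], ["pop"] * n, haps, gmap)


class TestPreprocess:
    def test_clean_panel_unchanged(self):
        panel = _panel_from_codes([[0, 2, 0], [2, 0, 0], [0, 0, 2]])
        out = preprocess_panel(panel)
        assert np.array_equal(out.haplotypes, panel.haplotypes)
        assert list(out.gmap.marker_id) == list(panel.gmap.marker_id)

    def test_high_missing_marker_removed(self):
        codes = np.zeros((10, 3), dtype=int)
        codes[:, 2] = 2
        codes[0, 1] = -9
        codes[1, 1] = -9  # marker m1: 20% missing
        out = preprocess_panel(_panel_from_codes(codes),
                               max_missing_marker=0.10)
        assert list(out.gmap.marker_id) == ["m0", "m2"]

    def test_high_missing_line_removed(self):
        codes = np.zeros((4, 10), dtype=int)
        codes[:, ::2] = 2
        codes[3, :2] = -9  # line L3: 20% missing
        out = preprocess_panel(_panel_from_codes(codes),
                               max_missing_marker=1.0, max_missing_line=0.10)
        assert list(out.line_ids) == ["L0", "L1", "L2"]

    def test_redundant_colocated_marker_dropped(self):
        codes = np.array([[0, 0, 2], [2, 2, 0], [0, 0, 0], [2, 2, 2]])
        out = preprocess_panel(_panel_from_codes(codes,
                                                 positions=[1.0, 1.0, 2.0]))
        assert list(out.gmap.marker_id) == ["m0", "m2"]

    def test_colocated_differing_markers_offset(self):
        codes = np.array([[0, 2], [2, 0], [0, 0], [2, 2]])
        out = preprocess_panel(_panel_from_codes(codes, positions=[1.0, 1.0]),
                               forced_offset_cM=0.01)
        assert out.gmap.position_cM[0] == pytest.approx(1.0)
        assert out.gmap.position_cM[1] == pytest.approx(1.01)

    def test_het_masked_and_mode_imputed(self):
        # marker 0: het in L0 -> missing -> imputed to the modal 2;
        # marker 1: mode tie (one 0, one 2 observed) -> first allele
        codes = np.array([[1, -9], [2, 0], [2, 2], [2, -9]])
        out = preprocess_panel(_panel_from_codes(codes),
                               max_missing_marker=1.0, max_missing_line=1.0)
        assert not out.has_missing()
        assert out.is_homozygous()
        d = out.dosage()
        assert d[0, 0] == 2
        assert d[0, 1] == 0 and d[3, 1] == 0

    def test_all_missing_locus_errors(self):
        codes = np.array([[1, 0], [1, 2], [-9, 0]])
        with pytest.raises(ValueError, match="m0"):
            preprocess_panel(_panel_from_codes(codes),
                             max_missing_marker=1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_always_clean(self, seed):
        r = np.random.default_rng(seed)
        codes = r.choice([0, 1, 2, -9], size=(8, 12), p=[0.4, 0.1, 0.4, 0.1])
        codes[0] = 0
        codes[1] = 2  # keep every locus imputable and polymorphic pre-filter
        panel = _panel_from_codes(codes)
        try:
            out = preprocess_panel(panel)
        except ValueError:
            return  # a fully-missing locus after masking is a legal rejection
        assert not out.has_missing()
        assert out.is_homozygous()


class TestIO:
    def test_roundtrip_calls_dialect(self, tmp_path, small_panel):
        g, m = tmp_path / "g.csv", tmp_path / "m.csv"
        write_genotype_matrix(small_panel, g, m)
        back = load_genotype_matrix(g, m, preprocess=False)
        assert np.array_equal(back.haplotypes, small_panel.haplotypes)
        assert list(back.gmap.marker_id) == list(small_panel.gmap.marker_id)

    def test_roundtrip_numeric_dialect(self, tmp_path, small_panel):
        g, m = tmp_path / "g.csv", tmp_path / "m.csv"
        write_genotype_matrix(small_panel, g, m, dialect="numeric")
        back = load_genotype_matrix(g, m, preprocess=False)
        assert np.array_equal(back.haplotypes, small_panel.haplotypes)

    def test_marker_missing_from_map_errors(self, tmp_path):
        (tmp_path / "g.csv").write_text("id,m0,m1\nL0,AA,BB\nL1,BB,AA\n")
        (tmp_path / "m.csv").write_text("marker_id,chromosome,cM\nm0,1,0.0\n")
        with pytest.raises(ValueError, match="m1"):
            load_genotype_matrix(tmp_path / "g.csv", tmp_path / "m.csv")

    def test_unparseable_call_errors(self, tmp_path):
        (tmp_path / "g.csv").write_text("id,m0\nL0,AA\nL1,XY\n")
        (tmp_path / "m.csv").write_text("marker_id,chromosome,cM\nm0,1,0.0\n")
        with pytest.raises(ValueError, match="XY"):
            load_genotype_matrix(tmp_path / "g.csv", tmp_path / "m.csv")

    def test_duplicate_line_ids_error(self, tmp_path):
        (tmp_path / "g.csv").write_text("id,m0\nL0,AA\nL0,BB\n")
        (tmp_path / "m.csv").write_text("marker_id,chromosome,cM\nm0,1,0.0\n")
        with pytest.raises(ValueError, match="L0"):
            load_genotype_matrix(tmp_path / "g.csv", tmp_path / "m.csv")

    def test_load_applies_redundancy_rule(self, tmp_path):
        (tmp_path / "g.csv").write_text(
            "id,m0,m1,m2\nL0,AA,AA,BB\nL1,BB,BB,AA\nL2,AA,AA,AA\nL3,BB,BB,BB\n")
        (tmp_path / "m.csv").write_text(
            "marker_id,chromosome,cM\nm0,1,3.0\nm1,1,3.0\nm2,1,5.0\n")
        panel = load_genotype_matrix(tmp_path / "g.csv", tmp_path / "m.csv")
        assert list(panel.gmap.marker_id) == ["m0", "m2"]
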