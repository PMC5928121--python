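"""Hi-C stage: interval parsing, decay regression, enrichment, the
Welch comparison, and the synthetic generators."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from sbstraffic.hic import (
    ContactMatrixBinned,
    GenomicIntervalSet,
    contact_decay,
    decay_at_intervals,
    hot_loop_enrichment,
    read_genome_sizes,
    read_intervals,
    read_matrix,
    synth_hic,
    synth_intervals,
)


class TestReadIntervals:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr2\t0\t50\n")
        ivs = read_intervals(p, "bed")
        assert len(ivs) == 2
        row = ivs.df.iloc[0]
        assert (row["chrom"], row["start"], row["end"]) == ("chr1", 100, 200)

    def test_fasta_header_dialect_matches_bed(self, tmp_path):
        # 1-based inclusive chr1:101-200 is the same region as BED 100-200
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\n")
        fa = tmp_path / "a.fasta"
        fa.write_text(">chr1:101-200 some description\nACGT\n")
        from_bed = read_intervals(bed, "bed")
        from_fa = read_intervals(fa, "hot-fasta-headers")
        pd.testing.assert_frame_equal(from_bed.df, from_fa.df)

    def test_arrowhead_domain_bodies(self, tmp_path):
        p = tmp_path / "domains.txt"
        p.write_text(
            "chr1\tx1\tx2\tchr2\ty1\ty2\tcolor\n"
            "1\t700000\t820000\t1\t700000\t820000\t255,255,0\n"
            "7\t1000000\t1100000\t7\t1000000\t1100000\t255,255,0\n"
        )
        ivs = read_intervals(p, "arrowhead-domainlist")
        assert list(ivs.df["chrom"]) == ["chr1", "chr7"]
        assert list(ivs.df["start"]) == [700000, 1000000]
        assert list(ivs.df["end"]) == [820000, 1100000]

    def test_arrowhead_anchor_interpretation(self, tmp_path):
        p = tmp_path / "domains.txt"
        p.write_text("1\t700000\t820000\t1\t700000\t820000\t255,255,0\n")
        ivs = read_intervals(p, "arrowhead-domainlist", interpretation="anchors",
                             anchor_width=25000)
        assert len(ivs) == 2
        assert list(ivs.df["start"]) == [700000, 795000]
        assert list(ivs.df["end"]) == [725000, 820000]

    def test_empty_file_warns_and_returns_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        with pytest.warns(UserWarning, match="no intervals"):
            ivs = read_intervals(p, "bed")
        assert len(ivs) == 0

    def test_malformed_record_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\toops\t300\n")
        with pytest.raises(ValueError, match="line 2"):
            read_intervals(p, "bed")

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1\t2\n")
        with pytest.raises(ValueError, match="dialect"):
            read_intervals(p, "gff")

    def test_start_must_precede_end(self):
        with pytest.raises(ValueError):
            GenomicIntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [10],
                                             "end": [10]}))


class TestIntervalSetOps:
    def test_merge_unions_overlaps(self):
        ivs = GenomicIntervalSet(pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [0, 50, 200, 10],
            "end": [100, 150, 300, 20],
        }))
        merged = ivs.merged().df
        assert list(merged.itertuples(index=False, name=None)) == [
            ("chr1", 0, 150), ("chr1", 200, 300), ("chr2", 10, 20),
        ]
        assert ivs.footprint() == 150 + 100 + 10

    def test_merge_agrees_with_intervaltree(self, rng):
        intervaltree = pytest.importorskip("intervaltree")
        starts = rng.integers(0, 10_000, 200)
        ends = starts + rng.integers(1, 500, 200)
        ivs = GenomicIntervalSet(pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": ends,
        }))
        tree = intervaltree.IntervalTree.from_tuples(zip(starts, ends))
        tree.merge_overlaps(strict=False)
        expect = sorted((iv.begin, iv.end) for iv in tree)
        got = list(ivs.merged().df[["start", "end"]].itertuples(index=False, name=None))
        assert got == expect


class TestContactDecay:
    @pytest.mark.parametrize("alpha", [-1.0, -1.5])
    def test_recovers_exact_power_law(self, alpha):
        cm, _ = synth_hic(n_bins=120, alpha_background=alpha, seed=0)
        prof = contact_decay(cm)
        interior = prof.alphas[20:-20]
        assert np.all(np.abs(interior - alpha) < 1e-6)

    def test_constant_matrix_gives_zero_slope(self):
        cm = ContactMatrixBinned(np.ones((60, 60)), bin_size=50_000)
        prof = contact_decay(cm)
        assert np.allclose(prof.alphas[np.isfinite(prof.alphas)], 0.0, atol=1e-12)

    def test_all_zero_row_is_missing_not_zero(self):
        m = np.abs(np.arange(60)[:, None] - np.arange(60)[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            m = np.where(m > 0, m**-1.0, 1.0)
        m[5, :] = 0.0
        m[:, 5] = 0.0
        prof = contact_decay(ContactMatrixBinned(m, bin_size=50_000))
        assert np.isnan(prof.alphas[5])

    def test_uses_at_most_flank_windows_each_side(self):
        cm, _ = synth_hic(n_bins=100, alpha_background=-1.2, seed=0)
        prof = contact_decay(cm, flank=20)
        assert prof.n_points.max() <= 40

    def test_bedgraph_export(self, tmp_path):
        cm, _ = synth_hic(n_bins=50, seed=0)
        prof = contact_decay(cm)
        out = tmp_path / "decay.bedgraph"
        prof.to_bedgraph(out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == np.isfinite(prof.alphas).sum()
        chrom, start, end, val = lines[0].split("\t")
        assert chrom == "chr1" and int(end) - int(start) == 50_000


class TestEnrichment:
    def _toy_sets(self, n_hots, overlap_count, genome=1_000_000, loop_frac=0.1):
        loop_len = int(genome * loop_frac)
        loops = GenomicIntervalSet(pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [loop_len]}), role="loop")
        rows = []
        for k in range(n_hots):
            if k < overlap_count:
                mid = 1000 + k * 50
            else:
                mid = loop_len + 1000 + k * 50
            rows.append(("chr1", mid - 5, mid + 5))
        hots = GenomicIntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                                  role="HOT")
        return hots, loops, {"chr1": genome}

    def test_upper_tail_binomial_against_exact_summation(self):
        hots, loops, sizes = self._toy_sets(100, 10)
        res = hot_loop_enrichment(hots, loops, sizes)
        assert res.n_hots == 100 and res.n_overlapping == 10
        assert res.n_expected == pytest.approx(10.0)
        # independent oracle: exact tail sum with integer combinatorics
        p = 0.1
        tail = sum(math.comb(100, k) * p**k * (1 - p) ** (100 - k)
                   for k in range(10, 101))
        assert res.p_value == pytest.approx(tail, rel=1e-12)
        assert res.p_value == pytest.approx(0.5487, abs=5e-4)

    def test_all_hots_inside_loops(self):
        hots, loops, sizes = self._toy_sets(50, 50)
        res = hot_loop_enrichment(hots, loops, sizes)
        assert res.n_overlapping == 50
        assert res.p_value < 1e-30

    def test_no_loops(self):
        hots, _, sizes = self._toy_sets(20, 0)
        empty = GenomicIntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                                   role="loop")
        res = hot_loop_enrichment(hots, empty, sizes)
        assert res.n_overlapping == 0 and res.n_expected == 0.0

    def test_missing_chromosome_size_is_an_error(self):
        hots, loops, _ = self._toy_sets(5, 1)
        with pytest.raises(ValueError, match="absent"):
            hot_loop_enrichment(hots, loops, {"chr2": 100})

    def test_any_overlap_rule_counts_edge_touchers(self):
        loops = GenomicIntervalSet(pd.DataFrame({
            "chrom": ["chr1"], "start": [1000], "end": [2000]}))
        hots = GenomicIntervalSet(pd.DataFrame({
            "chrom": ["chr1"], "start": [1990], "end": [2990]}))
        sizes = {"chr1": 100_000}
        mid = hot_loop_enrichment(hots, loops, sizes, rule="midpoint")
        any_ = hot_loop_enrichment(hots, loops, sizes, rule="any-overlap")
        assert mid.n_overlapping == 0 and any_.n_overlapping == 1

    def test_json_round_trip(self, tmp_path):
        hots, loops, sizes = self._toy_sets(10, 2)
        res = hot_loop_enrichment(hots, loops, sizes)
        out = tmp_path / "enrichment.json"
        res.to_json(out)
        data = json.loads(out.read_text())
        assert data["n_overlapping"] == 2


class TestDecayAtIntervals:
    def _profile(self, alphas):
        from sbstraffic.hic import DecayProfile

        a = np.asarray(alphas, float)
        return DecayProfile(alphas=a, n_points=np.full(a.size, 40),
                            chrom="chr1", bin_size=50_000, flank=20)

    def _hots_at_windows(self, windows, bin_size=50_000):
        rows = [("chr1", w * bin_size + 10_000, w * bin_size + 11_000)
                for w in windows]
        return GenomicIntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def test_identical_samples_give_p_one(self, rng):
        alphas = -1.2 + 0.1 * rng.standard_normal(50)
        prof = self._profile(alphas)
        hots = self._hots_at_windows(range(50))
        res = decay_at_intervals(prof, hots)
        assert res.delta == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_flagged(self):
        # every estimate identical: the Welch machinery is undefined and
        # must be flagged rather than reported as a zero p-value
        prof = self._profile([-1.2] * 15)
        hots = self._hots_at_windows(range(10, 15))
        res = decay_at_intervals(prof, hots)
        assert res.degenerate is True
        assert res.delta == pytest.approx(0.0)
        assert np.isnan(res.p_value)

    def test_welch_statistic_matches_textbook_formula(self, rng):
        a = -1.2 + 0.15 * rng.standard_normal(400)
        b_vals = -1.4 + 0.2 * rng.standard_normal(60)
        alphas = np.concatenate([a, b_vals])
        prof = self._profile(alphas)
        hots = self._hots_at_windows(range(400, 460))
        res = decay_at_intervals(prof, hots)
        sample_a = alphas  # all windows
        sample_b = b_vals
        va, vb = sample_a.var(ddof=1), sample_b.var(ddof=1)
        na, nb = sample_a.size, sample_b.size
        se2 = va / na + vb / nb
        t_expect = (sample_a.mean() - sample_b.mean()) / np.sqrt(se2)
        df_expect = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        assert res.statistic == pytest.approx(t_expect, rel=1e-12)
        assert res.df == pytest.approx(df_expect, rel=1e-12)
        assert res.ci_low < res.delta < res.ci_high

    def test_empty_hot_sample_is_an_error(self):
        prof = self._profile([-1.2] * 10)
        hots = self._hots_at_windows([500])  # outside the profile
        with pytest.raises(ValueError, match="no HOT"):
            decay_at_intervals(prof, hots)


class TestSynthHic:
    def test_same_seed_identical(self):
        a, _ = synth_hic(n_bins=80, noise_dispersion=0.3, seed=9)
        b, _ = synth_hic(n_bins=80, noise_dispersion=0.3, seed=9)
        assert np.array_equal(a.matrix, b.matrix)

    def test_different_seed_differs(self):
        a, _ = synth_hic(n_bins=80, noise_dispersion=0.3, seed=9)
        b, _ = synth_hic(n_bins=80, noise_dispersion=0.3, seed=10)
        assert not np.array_equal(a.matrix, b.matrix)

    def test_patch_windows_decay_faster(self):
        cm, truth = synth_hic(
            n_bins=200, alpha_background=-1.0,
            alpha_patches=(((70, 131), -1.5),), seed=3,
        )
        prof = contact_decay(cm)
        # windows more than one flank inside the patch recover exactly
        assert np.allclose(prof.alphas[95:106], -1.5, atol=1e-6)
        assert np.allclose(prof.alphas[25:45], -1.0, atol=1e-6)

    def test_positive_exponent_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            synth_hic(alpha_background=0.5)

    def test_loop_peak_raises_local_signal(self):
        base, _ = synth_hic(n_bins=100, seed=0)
        peaked, _ = synth_hic(n_bins=100, loop_peaks=((20, 70, 5.0),), seed=0)
        assert peaked.matrix[20, 70] > base.matrix[20, 70]
        assert np.allclose(peaked.matrix, peaked.matrix.T)

    def test_matrix_text_round_trips(self, tmp_path):
        cm, _ = synth_hic(n_bins=30, noise_dispersion=0.2, seed=4)
        dense = tmp_path / "dense.tsv"
        sparse = tmp_path / "sparse.tsv"
        cm.to_dense_text(dense)
        cm.to_sparse_text(sparse)
        back_d = read_matrix(dense)
        back_s = read_matrix(sparse)
        assert np.allclose(back_d.matrix, cm.matrix, rtol=1e-8)
        assert np.allclose(back_s.matrix, cm.matrix, rtol=1e-8)


class TestSynthIntervals:
    def test_enriched_case_recovers_rho(self):
        sizes = {"chr1": 50_000_000, "chr2": 50_000_000}
        hots, loops, truth = synth_intervals(
            n_hots=1000, n_loops=20, loop_length=200_000,
            genome_sizes=sizes, enrichment_rho=4.0, seed=5,
        )
        res = hot_loop_enrichment(hots, loops, sizes)
        assert truth["p_null"] == pytest.approx(0.04, abs=0.005)
        assert res.n_expected == pytest.approx(1000 * truth["p_null"], rel=1e-9)
        # ~4-fold enrichment: roughly 160 observed against ~40 expected
        assert 120 <= res.n_overlapping <= 200
        assert res.p_value < 1e-9

    def test_no_loops_leaves_all_hots_outside(self):
        hots, loops, truth = synth_intervals(n_hots=50, n_loops=0, seed=1)
        assert len(loops) == 0
        assert truth["n_inside_realized"] == 0

    def test_infeasible_rho_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth_intervals(n_hots=10, n_loops=100, loop_length=2_000_000,
                            genome_sizes={"chr1": 10_000_000},
                            enrichment_rho=50.0, seed=0)

    def test_same_seed_identical(self):
        a = synth_intervals(seed=3)[0].df
        b = synth_intervals(seed=3)[0].df
        pd.testing.assert_frame_equal(a, b)


def test_read_genome_sizes(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("chr1\t248956422\nchr2\t242193529\n")
    sizes = read_genome_sizes(p)
    assert sizes == {"chr1": 248956422, "chr2": 242193529}
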