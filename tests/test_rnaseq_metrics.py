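"""Coverage, metagene, junction and enrichment metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnp_atlas import rnaseq_metrics as rm
from mrnp_atlas import synthetic_data as sd
from mrnp_atlas.rnaseq_metrics import CoverageProfile


def brute_force_depth(blocks_per_read, length):
    depth = np.zeros(length, dtype=int)
    for blocks in blocks_per_read:
        for s, e in blocks:
            for p in range(s, e):
                depth[p] += 1
    return depth


class TestCoverageProfile:
    def test_single_read(self, sam_writer):
        path = sam_writer({"T1": 200}, [{"ref": "T1", "pos": 10, "cigar": "75M"}])
        prof = rm.coverage_profile(path, "T1")
        expected = np.zeros(200, dtype=int)
        expected[10:85] = 1
        assert np.array_equal(prof.depth, expected)

    def test_split_read_gap_uncovered(self, sam_writer):
        path = sam_writer({"T1": 400}, [{"ref": "T1", "pos": 0, "cigar": "30M200N45M"}])
        prof = rm.coverage_profile(path, "T1")
        assert prof.depth[:30].sum() == 30
        assert prof.depth[30:230].sum() == 0
        assert prof.depth[230:275].sum() == 45

    def test_indels_are_coverage_neutral(self, sam_writer):
        # 10M2I10M consumes 20 reference nt; 10M3D10M consumes 23 with the deletion uncovered
        path = sam_writer(
            {"T1": 100},
            [
                {"ref": "T1", "pos": 0, "cigar": "10M2I10M"},
                {"ref": "T1", "pos": 50, "cigar": "10M3D10M"},
            ],
        )
        depth = rm.coverage_profile(path, "T1").depth
        assert depth[:20].sum() == 20
        assert np.array_equal(depth[50:73], [1] * 10 + [0] * 3 + [1] * 10)

    def test_missing_transcript_raises(self, sam_writer):
        path = sam_writer({"T1": 100}, [])
        with pytest.raises(KeyError):
            rm.coverage_profile(path, "T9")

    def test_matches_brute_force_oracle(self, sam_writer, rng):
        length = 300
        reads, blocks = [], []
        for _ in range(50):
            pos = int(rng.integers(0, length - 80))
            if rng.random() < 0.3:
                gap = int(rng.integers(10, 50))
                a, b = 30, 40
                if pos + a + gap + b > length:
                    continue
                reads.append({"ref": "T1", "pos": pos, "cigar": f"{a}M{gap}N{b}M"})
                blocks.append([(pos, pos + a), (pos + a + gap, pos + a + gap + b)])
            else:
                reads.append({"ref": "T1", "pos": pos, "cigar": "75M"})
                blocks.append([(pos, pos + 75)])
        path = sam_writer({"T1": length}, reads)
        prof = rm.coverage_profile(path, "T1")
        assert np.array_equal(prof.depth, brute_force_depth(blocks, length))

    def test_truncated_sample_is_five_prime_biased(self, tmp_path):
        cfg = sd.GeneratorConfig(
            n_transcripts=50,
            n_read_pairs=20000,
            intron_fraction=0.0,
            mito_fraction=0.0,
            truncation_fraction={"eluate": 0.5},
            seed=8,
        )
        tr = sd.generate_transcriptome(cfg)
        path = tmp_path / "e.sam"
        sd.simulate_reads(tr, cfg, "eluate", 8, str(path), mode="transcript")
        profiles = rm.coverage_profiles(str(path))
        five, three = [], []
        for p in profiles.values():
            decile = len(p) // 10
            five.append(p.depth[:decile].mean())
            three.append(p.depth[-decile:].mean())
        assert np.mean(five) > np.mean(three)


class TestMetagene:
    def test_constant_profile_scales_to_zero(self):
        mg = rm.metagene_matrix([CoverageProfile("t", np.full(500, 7))], 100)
        assert np.array_equal(mg.matrix[0], np.zeros(100))

    def test_decreasing_profile_maps_one_to_zero(self):
        depth = np.arange(1000, 0, -1)
        mg = rm.metagene_matrix([CoverageProfile("t", depth)], 100)
        row = mg.matrix[0]
        assert row[0] == 1.0 and row[-1] == 0.0
        assert (np.diff(row) < 0).all()

    def test_shape_and_ranges(self, rng):
        profiles = [
            CoverageProfile(f"t{i}", rng.integers(0, 50, size=int(rng.integers(150, 900))))
            for i in range(12)
        ]
        mg = rm.metagene_matrix(profiles, 100)
        assert mg.matrix.shape == (12, 100)
        assert (mg.matrix >= 0).all() and (mg.matrix <= 1).all()
        assert mg.column_summary.min() >= 0 and mg.column_summary.max() <= 100
        assert mg.column_summary.max() == 100.0

    def test_profile_shorter_than_bins(self):
        mg = rm.metagene_matrix([CoverageProfile("t", np.arange(40))], 100)
        assert mg.matrix.shape == (1, 100)
        assert mg.matrix[0][0] == 0.0 and mg.matrix[0][-1] == 1.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            rm.metagene_matrix([CoverageProfile("t", np.ones(100))], subset=set())

    def test_truncation_shifts_column_summary(self, tmp_path):
        mats = {}
        for trunc in (0.0, 0.5):
            cfg = sd.GeneratorConfig(
                n_transcripts=60,
                n_read_pairs=25000,
                intron_fraction=0.0,
                mito_fraction=0.0,
                truncation_fraction={"eluate": trunc},
                seed=5,
            )
            tr = sd.generate_transcriptome(cfg)
            path = tmp_path / f"t{trunc}.sam"
            sd.simulate_reads(tr, cfg, "eluate", 5, str(path), mode="transcript")
            profiles = list(rm.coverage_profiles(str(path)).values())
            mats[trunc] = rm.metagene_matrix(profiles, 100).column_summary
        assert mats[0.5][0] > mats[0.0][0]
        assert mats[0.5][-1] < mats[0.0][-1]


class TestJunctionStats:
    def _write_site_reads(self, sam_writer, tiny, n_split, n_nonsplit):
        # txB: intron at genomic (650, 850); junction-spanning reads at the 5' site
        reads = []
        for _ in range(n_split):
            reads.append({"ref": "chr1", "pos": 620, "cigar": "30M200N45M"})
        for _ in range(n_nonsplit):
            reads.append({"ref": "chr1", "pos": 630, "cigar": "75M"})
        return sam_writer({"chr1": 2000}, reads)

    def test_retention_boundary_and_fraction(self, sam_writer, tiny_transcriptome):
        path = self._write_site_reads(sam_writer, tiny_transcriptome, 15, 5)
        stats = rm.junction_stats(path, tiny_transcriptome, min_cov=20)
        five = stats[stats["site"] == "5prime"]
        assert len(five) == 1
        assert five.iloc[0]["covered"] == 20
        assert five.iloc[0]["unspliced_fraction"] == pytest.approx(5 / 15)

    def test_below_threshold_excluded(self, sam_writer, tiny_transcriptome):
        path = self._write_site_reads(sam_writer, tiny_transcriptome, 10, 9)
        stats = rm.junction_stats(path, tiny_transcriptome, min_cov=20)
        assert stats[stats["site"] == "5prime"].empty

    def test_mismatched_gap_discarded(self, sam_writer, tiny_transcriptome):
        # gap starts at the annotated 5' site but ends elsewhere: neither split nor nonsplit
        reads = [{"ref": "chr1", "pos": 620, "cigar": "30M150N45M"}] * 25
        path = sam_writer({"chr1": 2000}, reads)
        stats = rm.junction_stats(path, tiny_transcriptome, min_cov=1)
        assert stats.empty

    def test_insufficient_anchor_not_counted(self, sam_writer, tiny_transcriptome):
        # contiguous reads ending 2 nt past the 5' splice site (650): anchor < 3
        reads = [{"ref": "chr1", "pos": 577, "cigar": "75M"}] * 25
        path = sam_writer({"chr1": 2000}, reads)
        stats = rm.junction_stats(path, tiny_transcriptome, min_cov=1, min_anchor=3)
        assert stats.empty

    def test_zero_retention_simulation_all_split(self, tmp_path):
        cfg = sd.GeneratorConfig(
            n_transcripts=30,
            intron_fraction=0.5,
            n_read_pairs=15000,
            retention_rate={"lysate": 0.0},
            seed=2,
        )
        tr = sd.generate_transcriptome(cfg)
        path = tmp_path / "g.sam"
        sd.simulate_reads(tr, cfg, "lysate", 2, str(path), mode="genome")
        stats = rm.junction_stats(str(path), tr, min_cov=20)
        assert not stats.empty
        assert (stats["unspliced_fraction"].dropna() == 0).all()

    def test_filter_monotone_in_min_cov(self, sam_writer, tiny_transcriptome, tmp_path):
        stats = sd.simulate_junction_counts(100, 0.2, 30.0, seed=4)
        retained = [
            (stats["covered"] >= min_cov).sum() for min_cov in (1, 10, 20, 40, 80)
        ]
        assert retained == sorted(retained, reverse=True)

    def test_nonpositive_intron_rejected(self, sam_writer):
        bad = sd.Transcriptome(
            transcripts=[
                sd.Transcript("t", "chr1", 0, mrna_length=100, intron_length=0, exon1_length=50)
            ],
            chrom_seq={},
            mature_seq={},
        )
        # force an inconsistent intron by constructing directly
        object.__setattr__(bad.transcripts[0], "intron_length", -5)
        path = sam_writer({"chr1": 500}, [])
        with pytest.raises(ValueError):
            rm.junction_stats(path, bad)


class TestCompareUnspliced:
    def test_identical_distributions_high_p(self, rng):
        frac = rng.random(300)
        df = pd.DataFrame({"unspliced_fraction": frac})
        stat, p, degenerate = rm.compare_unspliced(df, df.copy())
        assert not degenerate
        assert p > 0.9

    def test_symmetric_in_sample_order(self, rng):
        a = pd.DataFrame({"unspliced_fraction": rng.random(100)})
        b = pd.DataFrame({"unspliced_fraction": rng.random(120) * 2})
        _, p_ab, _ = rm.compare_unspliced(a, b)
        _, p_ba, _ = rm.compare_unspliced(b, a)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)

    def test_degenerate_all_identical(self):
        df = pd.DataFrame({"unspliced_fraction": [0.5] * 30})
        stat, p, degenerate = rm.compare_unspliced(df, df.copy())
        assert degenerate and np.isnan(p)

    def test_too_few_junctions_rejected(self):
        df = pd.DataFrame({"unspliced_fraction": [0.5]})
        with pytest.raises(ValueError):
            rm.compare_unspliced(df, df.copy())


class TestEnrichment:
    def test_global_scale_absorbed_by_size_factors(self, rng):
        lys = pd.Series(rng.integers(10, 1000, size=200), index=[f"t{i}" for i in range(200)])
        elu = 2 * lys
        table = rm.enrichment_table(lys, elu)
        assert np.allclose(table["log2fc"], 0.0, atol=1e-12)

    def test_equal_counts_zero_log2fc(self):
        lys = pd.Series([100, 100], index=["a", "b"])
        table = rm.enrichment_table(lys, lys.copy(), pseudocount=0.5)
        assert np.allclose(table["log2fc"], 0.0)
        assert (table["size_factor_lysate"] > 0).all()

    def test_all_zero_sample_rejected(self):
        lys = pd.Series([0, 0], index=["a", "b"])
        elu = pd.Series([5, 10], index=["a", "b"])
        with pytest.raises(ValueError):
            rm.enrichment_table(lys, elu)

    def test_log2fc_finite_with_zeros(self, rng):
        lys = pd.Series([0, 50, 100], index=["a", "b", "c"])
        elu = pd.Series([80, 0, 100], index=["a", "b", "c"])
        table = rm.enrichment_table(lys, elu)
        assert np.isfinite(table["log2fc"]).all()

    def test_length_effect_recovered_as_rank_correlation(self):
        cfg = sd.GeneratorConfig(
            n_transcripts=300,
            n_read_pairs=150_000,
            intron_fraction=0.0,
            mito_fraction=0.0,
            enrichment_coefficients=(0.0, 0.8),
            seed=13,
        )
        tr = sd.generate_transcriptome(cfg)
        table = rm.enrichment_table(
            sd.simulate_counts(tr, cfg, "lysate", 1),
            sd.simulate_counts(tr, cfg, "eluate", 2),
        )
        rho, _ = rm.correlate_enrichment(table, tr.table()["length"])
        assert rho > 0.3


class TestCorrelateEnrichment:
    def test_perfect_rank_agreement(self):
        records = pd.DataFrame(
            {"log2fc": [0.1, 0.5, 1.2, 3.0]}, index=["a", "b", "c", "d"]
        )
        cov = pd.Series([1.0, 2.0, 3.0, 4.0], index=records.index)
        rho, p = rm.correlate_enrichment(records, cov)
        assert rho == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        records = pd.DataFrame({"log2fc": [0.1, 0.5, 1.2]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            rm.correlate_enrichment(records, pd.Series([2.0, 2.0, 2.0], index=records.index))

    def test_too_few_shared_transcripts(self):
        records = pd.DataFrame({"log2fc": [0.1, 0.5]}, index=["a", "b"])
        with pytest.raises(ValueError):
            rm.correlate_enrichment(records, pd.Series([1.0, 2.0], index=records.index))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    depths=st.lists(st.integers(0, 40), min_size=5, max_size=200),
    n_bins=st.sampled_from([20, 100]),
)
def test_metagene_row_normalization_property(depths, n_bins):
    """Every row lies in [0, 1] with max 1 unless constant; summary max 100 unless flat."""
    mg = rm.metagene_matrix([CoverageProfile("t", np.array(depths))], n_bins)
    row = mg.matrix[0]
    assert row.min() >= 0 and row.max() <= 1
    binned_constant = len(set(np.round(row, 12))) == 1
    if not binned_constant:
        assert row.max() == 1.0
        assert mg.column_summary.max() == 100.0
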