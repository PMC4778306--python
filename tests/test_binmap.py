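"""Bin construction, map functions (Kosambi, RIL correction) and map summaries."""

import numpy as np
import pytest

from binqtl.binmap import (
    BinMap,
    BinMarker,
    UndefinedRFError,
    bin_stats,
    build_bins,
    build_genetic_map,
    collinearity_check,
    estimate_rf,
    kosambi,
    kosambi_inverse,
    mean_marker_spacing,
    ril_correct,
    ril_observed_rf,
)
from binqtl.calling import (
    BreakpointSet,
    ChromosomeBlocks,
    GenotypeBlock,
    EmptyInputError,
)
from binqtl.genome import ChromosomeSpec, ConfigurationError, GenomeSpec
from binqtl.snpmatrix import CALL_A, CALL_B, CALL_H, CALL_N


def _block(label: str, start_bp: int, end_bp: int) -> GenotypeBlock:
    return GenotypeBlock(label, -1, -1, start_bp, end_bp, -1, -1)


def _chrom_blocks(chrom: str, blocks) -> ChromosomeBlocks:
    return ChromosomeBlocks(chrom, blocks, np.empty(0, dtype=np.int64),
                            np.empty(0, dtype=np.int64), 15)


class TestBuildBins:
    def test_no_recombination_gives_one_bin_per_chromosome(self):
        spec = GenomeSpec([ChromosomeSpec("1", 1_000_000, 100.0)])
        blocks = {
            "R1": {"1": _chrom_blocks("1", [_block("A", 1000, 999_000)])},
            "R2": {"1": _chrom_blocks("1", [_block("B", 1000, 999_000)])},
        }
        bmap = build_bins(blocks, BreakpointSet([], {"R1": 0, "R2": 0}), spec)
        assert len(bmap) == 1
        b = bmap.bins[0]
        assert (b.start_bp, b.end_bp) == (1, 1_000_000)
        assert list(b.genotypes) == [CALL_A, CALL_B]

    def test_single_breakpoint_splits_chromosome_at_its_interval(self):
        """One RIL recombining inside grid interval k: two bins meeting at k."""
        spec = GenomeSpec([ChromosomeSpec("1", 1_000_000, 100.0)])
        # hom-hom transition gap 430-470 Kb -> midpoint 450 Kb -> interval k=4
        blocks = {
            "R1": {"1": _chrom_blocks("1", [_block("A", 1000, 430_000),
                                            _block("B", 470_000, 999_000)])},
            "R2": {"1": _chrom_blocks("1", [_block("A", 1000, 999_000)])},
        }
        bmap = build_bins(blocks, None, spec)
        assert len(bmap) == 2
        assert (bmap.bins[0].start_bp, bmap.bins[0].end_bp) == (1, 400_000)
        assert (bmap.bins[1].start_bp, bmap.bins[1].end_bp) == (400_001, 1_000_000)
        assert list(bmap.bins[0].genotypes) == [CALL_A, CALL_A]
        assert list(bmap.bins[1].genotypes) == [CALL_B, CALL_A]

    def test_het_only_coverage_labels_bin_heterozygous(self):
        spec = GenomeSpec([ChromosomeSpec("1", 300_000, 50.0)])
        blocks = {"R1": {"1": _chrom_blocks("1", [_block("H", 1000, 299_000)])}}
        bmap = build_bins(blocks, None, spec)
        assert list(bmap.bins[0].genotypes) == [CALL_H]

    def test_uncovered_bin_is_missing(self):
        spec = GenomeSpec([ChromosomeSpec("1", 300_000, 50.0)])
        blocks = {"R1": {}}
        bmap = build_bins(blocks, None, spec)
        assert list(bmap.bins[0].genotypes) == [CALL_N]

    def test_invalid_bin_unit_rejected(self):
        spec = GenomeSpec([ChromosomeSpec("1", 300_000, 50.0)])
        with pytest.raises(ConfigurationError):
            build_bins({}, None, spec, bin_unit=0)

    def test_bins_tile_chromosomes_exactly(self, small_spec, clean_pipeline):
        bmap = clean_pipeline["binmap"]
        for chrom in small_spec.chromosomes:
            sub = bmap.subset_chromosome(chrom.name)
            assert sub.bins[0].start_bp == 1
            assert sub.bins[-1].end_bp == chrom.bp_length
            for left, right in zip(sub.bins[:-1], sub.bins[1:]):
                assert right.start_bp == left.end_bp + 1
            assert all(b.start_bp % 100_000 == 1 for b in sub.bins)

    def test_no_homozygous_genotype_change_within_bins(self, clean_pipeline):
        """Every hom-to-hom transition midpoint falls on a bin start interval."""
        from binqtl.binmap import _recombination_events

        bmap = clean_pipeline["binmap"]
        boundary = set()
        for ril, by_chrom in clean_pipeline["blocks"].items():
            for chrom, cb in by_chrom.items():
                for left_bp, right_bp in _recombination_events(cb):
                    boundary.add((chrom, ((left_bp + right_bp) // 2 - 1) // 100_000))
        for b in bmap.bins:
            lo = (b.start_bp - 1) // 100_000
            hi = (b.end_bp - 1) // 100_000
            flags = [(b.chrom, k) in boundary for k in range(lo, hi + 1)]
            # events only in the leading boundary run; the bin body is clean
            if False in flags:
                first_clean = flags.index(False)
                assert not any(flags[first_clean:])


class TestBinStats:
    def test_hand_countable_two_bin_summary(self):
        bins = [
            BinMarker("mk1", "1", 1, 100_000, np.array([0], dtype=np.int8)),
            BinMarker("mk2", "1", 100_001, 400_000, np.array([3], dtype=np.int8)),
        ]
        stats = bin_stats(BinMap(bins, ["R1"]))
        assert stats["mean_length_bp"] == 200_000
        assert stats["median_length_bp"] == 200_000
        assert stats["fraction_below_0.5Mb"] == 1.0
        assert stats["missing_rate"] == 0.5
        assert stats["bins_above_10Mb"] == []

    def test_recount_oracle_on_simulated_map(self, clean_pipeline):
        bmap = clean_pipeline["binmap"]
        stats = bin_stats(bmap)
        lengths = [b.end_bp - b.start_bp + 1 for b in bmap.bins]
        assert stats["n_bins"] == len(lengths)
        assert stats["mean_length_bp"] == pytest.approx(np.mean(lengths))
        assert stats["fraction_below_0.5Mb"] == pytest.approx(
            sum(1 for L in lengths if L < 0.5e6) / len(lengths)
        )

    def test_empty_map_rejected(self):
        with pytest.raises(EmptyInputError):
            bin_stats(BinMap([], []))


class TestMapFunctions:
    def test_rf_identical_vectors_zero(self):
        g = np.array([0, 1, 0, 1], dtype=np.int8)
        assert estimate_rf(g, g) == (0.0, 4)

    def test_rf_counting_oracle(self, rng):
        g_i = rng.integers(0, 2, size=300).astype(np.int8)
        g_j = g_i.copy()
        flip = rng.choice(300, size=10, replace=False)
        g_j[flip] = 1 - g_j[flip]
        rhat, n = estimate_rf(g_i, g_j)
        assert n == 300
        assert rhat == pytest.approx(10 / 300)

    def test_rf_excludes_het_and_missing(self):
        g_i = np.array([0, 2, 0, 3, 1], dtype=np.int8)
        g_j = np.array([1, 0, 0, 1, 1], dtype=np.int8)
        rhat, n = estimate_rf(g_i, g_j)
        assert (rhat, n) == (pytest.approx(1 / 3), 3)

    def test_rf_complementary_vectors_flag_ordering_violation(self):
        g = np.array([0, 1, 0], dtype=np.int8)
        rhat, _ = estimate_rf(g, 1 - g)
        assert rhat == 1.0

    def test_rf_undefined_without_informative_pairs(self):
        g = np.array([2, 3], dtype=np.int8)
        with pytest.raises(UndefinedRFError):
            estimate_rf(g, g)

    @pytest.mark.parametrize("rhat, expected", [(0.0, 0.0), (0.2, 0.125)])
    def test_ril_correction_closed_form(self, rhat, expected):
        assert ril_correct(rhat) == pytest.approx(expected, abs=1e-12)

    def test_ril_correction_fixed_point_at_free_recombination(self):
        assert ril_correct(0.5, clamp=False) == pytest.approx(0.5)

    def test_ril_correction_rejects_negative(self):
        with pytest.raises(ValueError):
            ril_correct(-0.01)

    def test_kosambi_values(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.1) == pytest.approx(25 * np.log(1.2 / 0.8), abs=1e-12)
        assert kosambi(0.1) == pytest.approx(10.137, abs=1e-3)
        with pytest.raises(ValueError):
            kosambi(0.5)

    def test_kosambi_round_trip_and_monotonicity(self):
        r = np.linspace(0.0, 0.49, 200)
        assert np.max(np.abs(kosambi_inverse(kosambi(r)) - r)) < 1e-10
        d = kosambi(r)
        assert np.all(np.diff(d) > 0)

    def test_haldane_waddington_round_trip(self):
        r = np.linspace(0.0, 0.49, 100)
        back = np.array([ril_correct(ril_observed_rf(x), clamp=False) for x in r])
        assert np.max(np.abs(back - r)) < 1e-10

    def test_kosambi_of_corrected_rf_is_monotone(self):
        rhat = np.linspace(0.0, 0.49, 100)
        d = np.array([kosambi(ril_correct(x)) for x in rhat])
        assert np.all(np.diff(d) > 0)


class TestGeneticMap:
    def _map_from_vectors(self, vectors):
        bins = [
            BinMarker(f"mk{i+1}", "1", i * 100_000 + 1, (i + 1) * 100_000,
                      np.asarray(v, dtype=np.int8))
            for i, v in enumerate(vectors)
        ]
        return BinMap(bins, [f"R{j+1}" for j in range(len(vectors[0]))])

    def test_identical_bins_give_zero_length_chromosome(self):
        g = [0, 1, 0, 1, 1]
        gmap = build_genetic_map(self._map_from_vectors([g, g, g]))
        assert gmap.chromosome_cm("1") == 0.0

    def test_undefined_rf_recorded_as_gap_warning(self):
        gmap = build_genetic_map(self._map_from_vectors([[0, 1], [2, 2], [0, 1]]))
        assert len(gmap.warnings) == 2
        assert gmap.chromosome_cm("1") == 0.0

    def test_map_recovery_on_simulation(self, small_spec):
        """Estimated chromosome lengths within 10% of the simulated 120 cM
        (median over 3 seeds, error-free fully observed calls)."""
        from binqtl import breed_ril_population, observe_gbs, filter_segregation
        from binqtl.calling import call_population, extract_breakpoints

        per_chrom = {c.name: [] for c in small_spec.chromosomes}
        for seed in (42, 43, 44):
            pop = breed_ril_population(small_spec, 300, 10, seed=seed)
            matrix = observe_gbs(pop, small_spec, 1.0, 0.0, seed=7)
            filtered, _ = filter_segregation(matrix)
            blocks = call_population(filtered)
            bmap = build_bins(blocks, extract_breakpoints(blocks), small_spec)
            gmap = build_genetic_map(bmap)
            for name in per_chrom:
                per_chrom[name].append(gmap.chromosome_cm(name))
        for name, values in per_chrom.items():
            assert abs(np.median(values) - 120.0) / 120.0 < 0.10

    def test_summary_uses_length_over_marker_count_convention(self, clean_pipeline):
        summary = clean_pipeline["gmap"].summary()
        row = summary.iloc[0]
        assert row["avg_spacing_cm"] == pytest.approx(
            mean_marker_spacing(row["genetic_cm"], row["n_markers"])
        )
        total = summary.iloc[-1]
        assert total["chrom"] == "Total"
        assert total["n_markers"] == summary["n_markers"][:-1].sum()


class TestCollinearity:
    def test_internally_built_map_is_collinear(self, clean_pipeline):
        report = collinearity_check(clean_pipeline["gmap"])
        assert (report["spearman_rho"] >= 0.9999).all()
        assert (report["n_misplaced"] == 0).all()

    def test_two_swapped_bins_flagged(self, clean_pipeline):
        gmap = clean_pipeline["gmap"]
        frame = gmap.frame.copy()
        chrom = frame["chrom"].iloc[0]
        idx = frame.index[frame["chrom"] == chrom][:40]
        # swap two well-separated markers' genetic coordinates
        i, j = idx[5], idx[30]
        frame.loc[[i, j], "cm"] = frame.loc[[j, i], "cm"].to_numpy()
        from binqtl.binmap import GeneticMap

        report = collinearity_check(GeneticMap(frame))
        row = report[report["chrom"] == chrom].iloc[0]
        assert row["n_misplaced"] == 2
        assert row["spearman_rho"] < 1.0
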