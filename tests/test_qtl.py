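"""QTL scan machinery: expectations, LOD regression, intervals, integration."""

import numpy as np
import pytest

from binqtl.binmap import BinMap, BinMarker, build_genetic_map, kosambi, ril_observed_rf
from binqtl.qtl import (
    EvalPoints,
    LODProfile,
    QTLResult,
    find_stable_qtl,
    genotype_expectations,
    integrate_pleiotropic,
    merge_intervals,
    permutation_threshold,
    scan,
    summarize_qtl,
    support_interval,
)
from binqtl.snpmatrix import CALL_A, CALL_B, CALL_H, CALL_N


def _binmap(vectors, chrom="1", spacing_bp=1_000_000):
    bins = [
        BinMarker(f"mk{i+1}", chrom, i * spacing_bp + 1, (i + 1) * spacing_bp,
                  np.asarray(v, dtype=np.int8))
        for i, v in enumerate(vectors)
    ]
    return BinMap(bins, [f"R{j+1}" for j in range(len(vectors[0]))])


def _points_from_matrix(X, chrom="1"):
    """Bare evaluation points for regression tests (one point per row of X)."""
    p = X.shape[0]
    return EvalPoints(
        point_id=np.array([f"mk{i+1}" for i in range(p)], dtype=object),
        chrom=np.full(p, chrom, dtype=object),
        cm=np.arange(p, dtype=float),
        bp=np.arange(1, p + 1) * 10**6,
        start_bp=np.arange(p) * 10**6 + 1,
        end_bp=np.arange(1, p + 1) * 10**6,
        bin_index=np.arange(p),
        X=np.asarray(X, dtype=float),
        ril_ids=[f"R{j+1}" for j in range(X.shape[1])],
    )


def _ril_two_locus_expectation(x_left, r1, x_right, r2):
    """Enumeration oracle: fixed-RIL genotype table for flank pair (L, R).

    States are A/B at the three loci; transition probability between fixed
    genotypes across an interval of meiotic fraction r is the
    Haldane-Waddington RIL mismatch probability R = 2r/(1+2r).
    """
    R1, R2 = ril_observed_rf(r1), ril_observed_rf(r2)
    total = {1: 0.0, -1: 0.0}
    for mid in (1, -1):
        p = (R1 if mid != x_left else 1 - R1) * (R2 if mid != x_right else 1 - R2)
        total[mid] = p
    z = total[1] + total[-1]
    return (total[1] - total[-1]) / z


class TestGenotypeExpectations:
    def test_observed_homozygous_bins_code_exactly(self):
        bmap = _binmap([[0, 1], [1, 0], [2, 3]])
        gmap = build_genetic_map(bmap)
        pts = genotype_expectations(bmap, gmap, step=0.0)
        assert pts.X[0].tolist() == [-1.0, 1.0]
        assert pts.X[1].tolist() == [1.0, -1.0]

    def test_missing_bin_midway_between_opposite_flanks_is_zero(self):
        # R1: A, missing, B; the other lines give equal RF (1/3) on both
        # flanking intervals, so the distances are symmetric
        vectors = [[0, 0, 1, 0], [3, 0, 1, 1], [1, 0, 1, 0]]
        bmap = _binmap(vectors)
        gmap = build_genetic_map(bmap)
        pts = genotype_expectations(bmap, gmap, step=0.0)
        assert pts.X[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matching_flanks_match_two_locus_enumeration_oracle(self):
        """A-hom flanks at r = 0.1 per side: E[x] = -12/13 ~ -0.923."""
        d = kosambi(0.1)
        expected = _ril_two_locus_expectation(-1, 0.1, -1, 0.1)
        assert expected == pytest.approx(-12 / 13)
        assert expected < -0.9

        # build a 3-bin map whose adjacent RFs reproduce r=0.1 per interval:
        # RIL mismatch probability R = 2r/(1+2r) = 1/6 -> 50 of 300 lines
        rng = np.random.default_rng(0)
        n = 300
        g1 = rng.integers(0, 2, n).astype(np.int8)
        flip1 = rng.choice(n, size=50, replace=False)
        g2 = g1.copy()
        g2[flip1] = 1 - g2[flip1]
        g3 = g2.copy()
        flip2 = rng.choice(n, size=50, replace=False)
        g3[flip2] = 1 - g3[flip2]
        target = 0  # a line with A at both flanks whose middle bin we blank
        g1[target] = g3[target] = 0
        g2[target] = 3  # missing
        bmap = _binmap([g1, g2, g3])
        gmap = build_genetic_map(bmap)
        r_hat = gmap.frame["r"].to_numpy()[1:]
        pts = genotype_expectations(bmap, gmap, step=0.0)
        oracle = _ril_two_locus_expectation(-1, r_hat[0], -1, r_hat[1])
        assert pts.X[1, target] == pytest.approx(oracle, abs=1e-10)
        assert pts.X[1, target] < -0.9

    def test_heterozygous_observation_codes_zero(self):
        bmap = _binmap([[0], [2], [1]])
        gmap = build_genetic_map(bmap)
        pts = genotype_expectations(bmap, gmap, step=0.0)
        assert pts.X[1, 0] == 0.0

    def test_pseudomarkers_interpolate_between_bins(self, clean_pipeline):
        bmap = clean_pipeline["binmap"]
        gmap = clean_pipeline["gmap"]
        pts = genotype_expectations(bmap, gmap, step=2.0)
        assert len(pts) > len(bmap)
        pseudo = pts.bin_index < 0
        assert pseudo.any()
        assert np.all(np.abs(pts.X[pseudo]) <= 1.0)


class TestScan:
    def test_constant_coding_gives_zero_lod(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        X = np.vstack([np.zeros(20), np.ones(20)])
        profile = scan(y, _points_from_matrix(X))
        assert np.allclose(profile.lod, 0.0)

    def test_lod_matches_closed_form_regression_oracle(self):
        """Fixed 12-line toy table: LOD equals the normal-equations solution."""
        y = np.array([181.2, 201.5, 190.3, 211.0, 185.7, 208.9,
                      179.4, 205.2, 188.8, 214.6, 183.1, 199.0])
        x = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0,
                      -1.0, 1.0, 0.0, 1.0, -1.0, 0.0])
        profile = scan(y, _points_from_matrix(x[None, :]))
        # independent oracle: explicit least squares via lstsq
        A = np.column_stack([np.ones_like(x), x])
        beta, rss1, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss0 = np.sum((y - y.mean()) ** 2)
        lod = (len(y) / 2) * np.log10(rss0 / rss1[0])
        assert profile.lod[0] == pytest.approx(lod, abs=1e-8)
        assert profile.effect[0] == pytest.approx(beta[1], abs=1e-8)
        assert profile.pve[0] == pytest.approx(100 * (1 - rss1[0] / rss0), abs=1e-8)

    def test_effect_sign_anchored_to_b_allele(self):
        rng = np.random.default_rng(3)
        x = rng.choice([-1.0, 1.0], size=100)
        y = 10.0 + 2.5 * x + rng.normal(0, 0.5, 100)  # B allele increases trait
        profile = scan(y, _points_from_matrix(x[None, :]))
        assert profile.effect[0] > 0

    def test_degenerate_phenotypes_rejected(self):
        X = np.ones((3, 12))
        with pytest.raises(ValueError):
            scan(np.full(12, 5.0), _points_from_matrix(X))
        with pytest.raises(ValueError):
            scan(np.array([1.0, 2.0] + [np.nan] * 10), _points_from_matrix(X))


class TestPermutationThreshold:
    def test_bit_identical_under_fixed_seed(self, rng):
        y = rng.normal(size=50)
        X = rng.choice([-1.0, 1.0], size=(30, 50))
        a = permutation_threshold(y, _points_from_matrix(X), n_perm=100, seed=5)
        b = permutation_threshold(y, _points_from_matrix(X), n_perm=100, seed=5)
        assert a.threshold == b.threshold
        assert np.array_equal(a.max_lods, b.max_lods)

    def test_effective_threshold_never_below_lod_floor(self, rng):
        y = rng.normal(size=50)
        X = rng.choice([-1.0, 1.0], size=(5, 50))
        res = permutation_threshold(y, _points_from_matrix(X), n_perm=100, seed=2)
        assert res.effective == max(res.threshold, 3.5)

    def test_too_few_permutations_rejected(self, rng):
        y = rng.normal(size=50)
        X = rng.choice([-1.0, 1.0], size=(5, 50))
        with pytest.raises(ValueError):
            permutation_threshold(y, _points_from_matrix(X), n_perm=50)


class TestSupportInterval:
    def _profile(self, lods, chrom="1"):
        X = np.zeros((len(lods), 4))
        pts = _points_from_matrix(X, chrom=chrom)
        return LODProfile("T", "E1", pts, np.asarray(lods, float),
                          np.zeros(len(lods)), np.zeros(len(lods)), 4)

    def test_sharp_peak_collapses_to_single_point(self):
        profile = self._profile([1.0, 5.0, 1.0])
        ci = support_interval(profile, 1)
        assert (ci.left_index, ci.right_index) == (1, 1)

    def test_drop_rule_on_toy_profile(self):
        """[2.0, 3.9, 5.0, 4.1, 3.2, 1.0]: the region with LOD >= 3.5."""
        profile = self._profile([2.0, 3.9, 5.0, 4.1, 3.2, 1.0])
        ci = support_interval(profile, 2, drop=1.5)
        assert (ci.left_index, ci.right_index) == (1, 3)
        assert ci.left_marker == "mk2" and ci.right_marker == "mk4"

    def test_interval_contains_peak_and_respects_bp_bounds(self):
        profile = self._profile([3.0, 4.0, 6.0, 5.5, 4.9, 4.6, 2.0])
        ci = support_interval(profile, 2)
        assert ci.left_index <= 2 <= ci.right_index
        assert ci.start_bp <= profile.points.bp[2] <= ci.end_bp


class TestQTLIntegration:
    def _result(self, name, trait, chrom, lo_mb, hi_mb, envs):
        return QTLResult(
            name=name, trait=trait, environments=envs, chrom=chrom,
            peak_id="mk", peak_bp=int((lo_mb + hi_mb) / 2 * 1e6),
            left_marker="mkL", right_marker="mkR",
            ci_start_bp=int(lo_mb * 1e6), ci_end_bp=int(hi_mb * 1e6),
            lod=5.0, pve=8.0, add=1.0,
        )

    def test_no_peaks_gives_empty_summary(self, rng):
        y = rng.normal(size=60)
        X = rng.choice([-1.0, 1.0], size=(20, 60))
        profile = scan(y, _points_from_matrix(X), trait="T", env="E1")
        assert summarize_qtl([profile], 10.0) == []

    def test_same_trait_peaks_merge_across_environments(self, rng):
        n = 200
        x = rng.choice([-1.0, 1.0], size=n)
        X = np.vstack([x, rng.choice([-1.0, 1.0], size=n)])
        profiles = []
        for env in ("E1", "E2"):
            y = 1.2 * x + rng.normal(0, 1.0, n)
            profiles.append(scan(y, _points_from_matrix(X), trait="PH", env=env))
        results = summarize_qtl(profiles, 3.5)
        assert len(results) == 1
        assert results[0].environments == ["E1", "E2"]
        assert results[0].name == "qPH1"
        assert results[0].lod == pytest.approx(
            np.mean([p.lod.max() for p in profiles]), abs=1e-9
        )

    def test_stability_requires_at_least_two_environments(self):
        single = self._result("qPH1", "PH", "1", 10, 20, ["E1"])
        multi = self._result("qPH2", "PH", "2", 10, 20, ["E1", "E2", "E3"])
        stable = find_stable_qtl([single, multi])
        assert [r.name for r in stable] == ["qPH2"]

    def test_pleiotropic_union_on_published_chr10_intervals(self):
        """qPH10 81.30-85.10, qEH10 80.10-94.70, qIN10 81.30-94.20 combine
        into one region spanning 80.10-94.70 Mb (14.6 Mb)."""
        results = [
            self._result("qPH10", "PH", "10", 81.30, 85.10, ["E1", "E2", "E3"]),
            self._result("qEH10", "EH", "10", 80.10, 94.70, ["E1", "E2", "E3"]),
            self._result("qIN10", "IN", "10", 81.30, 94.20, ["E2", "E3"]),
        ]
        pqtls = integrate_pleiotropic(results)
        assert len(pqtls) == 1
        p = pqtls[0]
        assert (p.start_bp, p.end_bp) == (int(80.10e6), int(94.70e6))
        assert p.physical_length_bp / 1e6 == pytest.approx(14.6, abs=0.01)
        assert p.n_member_detections == 8
        assert set(p.members) == {"qPH10", "qEH10", "qIN10"}

    def test_interval_union_oracle_on_chr1_intervals(self):
        merged = merge_intervals([(91.00, 98.40), (91.00, 111.70)])
        assert merged == [(91.00, 111.70)]
        assert merged[0][1] - merged[0][0] == pytest.approx(20.7)

    def test_qtl_on_different_chromosomes_do_not_combine(self):
        results = [
            self._result("qPH1", "PH", "1", 10, 20, ["E1"]),
            self._result("qEH2", "EH", "2", 10, 20, ["E1"]),
        ]
        assert integrate_pleiotropic(results) == []

    def test_single_trait_chains_do_not_qualify(self):
        results = [
            self._result("qPH1-1", "PH", "1", 10, 20, ["E1"]),
            self._result("qPH1-2", "PH", "1", 15, 30, ["E2"]),
        ]
        assert integrate_pleiotropic(results) == []

    def test_pqtl_interval_contains_every_member_ci(self):
        results = [
            self._result("qPH5", "PH", "5", 172.9, 178.6, ["E3"]),
            self._result("qEH5", "EH", "5", 175.0, 178.6, ["E3"]),
            self._result("qIN3", "IN", "3", 5.0, 9.0, ["E1"]),
            self._result("qPH3", "PH", "3", 8.0, 12.0, ["E1", "E2"]),
        ]
        for p in integrate_pleiotropic(results):
            members = [r for r in results if r.name in p.members]
            for m in members:
                assert p.start_bp <= m.ci_start_bp and m.ci_end_bp <= p.end_bp
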