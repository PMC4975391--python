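"""LOH mapping: het-SNP selection, skew calls, region delineation, copy status."""

import numpy as np
import pytest

from secondhit.loh_mapper import (
    CopyStatus,
    CoverageWindow,
    LohRegion,
    SkewCall,
    assess_copy_neutrality,
    call_skew,
    delineate_loh_regions,
    detect_homozygous_deletion,
    identify_candidate_snps_unpaired,
    identify_het_snps,
    unassigned_skewed_snps,
)
from secondhit.variant_io import SnpObservation


def snp(pos, taf=0.5, naf=0.5, depth=100, chrom="16"):
    ta = round(taf * depth)
    na = round(naf * depth)
    return SnpObservation(chrom, pos, depth - na, na, depth - ta, ta)


def track(tafs, start=1_000_000, spacing=100_000):
    return [snp(start + i * spacing, taf) for i, taf in enumerate(tafs)]


class TestHetSelection:
    def test_interior_point_kept(self):
        s = SnpObservation("16", 100, 26, 24, 30, 30)
        assert identify_het_snps([s]) == [s]

    def test_depth_must_exceed_19(self):
        s = SnpObservation("16", 100, 10, 9, 30, 30)  # depth 19, AF 0.47
        assert identify_het_snps([s]) == []
        s20 = SnpObservation("16", 100, 10, 10, 30, 30)
        assert identify_het_snps([s20]) == [s20]

    def test_af_bounds_inclusive(self):
        at_low = SnpObservation("16", 100, 60, 40, 1, 1)
        at_high = SnpObservation("16", 200, 40, 60, 1, 1)
        outside = SnpObservation("16", 300, 61, 39, 1, 1)
        assert identify_het_snps([at_low, at_high, outside]) == [at_low, at_high]

    def test_unpaired_track_redirected(self):
        s = SnpObservation("16", 100, 0, 0, 30, 30, paired=False)
        with pytest.raises(ValueError, match="unpaired"):
            identify_het_snps([s])

    def test_refilter_oracle_on_simulated_sites(self):
        rng = np.random.default_rng(7)
        sites = []
        for i in range(1000):
            depth = rng.poisson(80)
            alt = rng.binomial(depth, 0.5) if depth else 0
            sites.append(SnpObservation("16", i + 1, depth - alt, alt, 40, 40))
        kept = identify_het_snps(sites)
        oracle = [
            s for s in sites
            if s.normal_depth > 19 and 0.40 <= s.normal_alt / s.normal_depth <= 0.60
        ]
        assert kept == oracle


class TestUnpairedSelection:
    @pytest.mark.parametrize("taf,kept", [(0.96, False), (0.05, True), (0.95, True), (0.5, True)])
    def test_af_window(self, taf, kept):
        s = snp(100, taf=taf)
        assert (identify_candidate_snps_unpaired([s]) == [s]) is kept

    def test_homozygous_alt_site_rejected(self):
        rng = np.random.default_rng(0)
        depth = 80
        alt = rng.binomial(depth, 0.999)
        s = SnpObservation("16", 1, 0, 0, depth - alt, alt, paired=False)
        assert identify_candidate_snps_unpaired([s]) == []


class TestSkewCall:
    @pytest.mark.parametrize(
        "taf,expected",
        [(0.39, "skewed"), (0.40, "normal"), (0.50, "normal"), (0.60, "normal"), (0.61, "skewed")],
    )
    def test_boundaries(self, taf, expected):
        assert call_skew(snp(100, taf=taf)).value == expected

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError, match="zero tumor depth"):
            call_skew(SnpObservation("16", 1, 50, 50, 0, 0))


class TestDelineation:
    def test_telomere_anchored_region_of_3mb(self):
        tafs = [0.75] * 50 + [0.5] * 20
        snps = track(tafs, start=100_000, spacing=60_000)  # 50 skewed over ~3 Mb
        regions = delineate_loh_regions(snps)
        assert len(regions) == 1
        r = regions[0]
        assert r.telomere_anchored
        assert r.confident_start == 100_000
        assert r.confident_end == 100_000 + 49 * 60_000
        assert r.confident_width == pytest.approx(3e6, rel=0.03)
        assert r.uncertain_end == 100_000 + 50 * 60_000  # first normal SNP
        assert r.n_skewed == 50

    def test_all_normal_yields_nothing(self):
        assert delineate_loh_regions(track([0.5] * 40)) == []

    def test_run_below_min_skewed_reported_unassigned(self):
        snps = track([0.8] * 5 + [0.5] * 30)
        regions = delineate_loh_regions(snps)
        assert regions == []
        assert len(unassigned_skewed_snps(snps, regions)) == 5

    def test_interior_normal_counted_not_splitting(self):
        tafs = [0.8] * 12 + [0.5] + [0.8] * 12 + [0.5] * 10
        regions = delineate_loh_regions(track(tafs))
        assert len(regions) == 1
        assert regions[0].n_skewed == 24
        assert regions[0].n_discordant_interior == 1

    def test_isolated_skew_does_not_extend_boundary(self):
        # one lone skewed SNP well past the run must not drag the region end
        tafs = [0.8] * 20 + [0.5] * 4 + [0.8] + [0.5] * 10
        regions = delineate_loh_regions(track(tafs))
        assert len(regions) == 1
        assert regions[0].n_skewed == 20

    def test_confident_spans_disjoint_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            tafs = np.where(rng.random(150) < 0.4, 0.8, 0.5)
            regions = delineate_loh_regions(track(list(tafs)))
            spans = sorted((r.confident_start, r.confident_end) for r in regions)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
            for r in regions:
                assert r.n_skewed >= 10
                assert r.uncertain_start <= r.confident_start <= r.confident_end <= r.uncertain_end

    def test_multi_chromosome_track_rejected(self):
        snps = [snp(100, 0.8, chrom="16"), snp(200, 0.8, chrom="9")]
        with pytest.raises(ValueError, match="single-chromosome"):
            delineate_loh_regions(snps)


def region(start=2_000_000, end=8_000_000, chrom="16"):
    return LohRegion(chrom, start, end, start - 100_000, end + 100_000, n_skewed=30)


def windows(log2s, chrom="16", start=2_000_000, width=100_000):
    return [
        CoverageWindow(chrom, start + i * width, start + (i + 1) * width - 1, 2.0 ** v)
        for i, v in enumerate(log2s)
    ]


class TestCopyStatus:
    def test_flat_diploid_is_neutral(self):
        r = region()
        assert assess_copy_neutrality(r, windows([0.0] * 8)) is CopyStatus.neutral
        assert r.copy_status is CopyStatus.neutral

    def test_deep_depression_is_homozygous_loss(self):
        # purity 0.8 two-allele loss: 0.4 of 2 copies -> log2 = -2.32
        assert (
            assess_copy_neutrality(region(), windows([-2.32] * 8))
            is CopyStatus.homozygous_loss
        )

    def test_intermediate_depression_is_single_loss(self):
        # 1.47 of 2 copies -> log2 = -0.44
        assert (
            assess_copy_neutrality(region(), windows([-0.44] * 8))
            is CopyStatus.single_loss
        )

    def test_elevated_ratio_is_gain(self):
        assert assess_copy_neutrality(region(), windows([0.5] * 8)) is CopyStatus.gain

    def test_too_few_windows_indeterminate(self):
        assert (
            assess_copy_neutrality(region(), windows([0.0] * 4))
            is CopyStatus.indeterminate
        )


class TestHomozygousDeletionScan:
    def test_nested_focal_deletion_recovered(self):
        from secondhit.synthetic_data import homozygous_del_config, simulate_coverage_windows

        geo = homozygous_del_config()
        rng = np.random.default_rng(3)
        wins = simulate_coverage_windows(
            start=geo["start"], end=geo["end"], window=geo["window"],
            purity=geo["purity"], hom_del=geo["hom_del"],
            single_loss=geo["single_loss"], rng=rng,
        )
        intervals = detect_homozygous_deletion(wins)
        statuses = {iv.status for iv in intervals}
        assert statuses == {CopyStatus.single_loss, CopyStatus.homozygous_loss}
        env = next(iv for iv in intervals if iv.status is CopyStatus.single_loss)
        core = next(iv for iv in intervals if iv.status is CopyStatus.homozygous_loss)
        # nested: core inside envelope; sizes near 150 kb / 50 kb
        assert env.start <= core.start and core.end <= env.end
        assert (env.end - env.start) == pytest.approx(150_000, abs=2 * geo["window"])
        assert (core.end - core.start) == pytest.approx(50_000, abs=2 * geo["window"])

        # independent oracle: direct threshold scan over the same windows
        lost = [w.log2 <= -0.3 for w in wins]
        first, last = lost.index(True), len(lost) - 1 - lost[::-1].index(True)
        assert env.start == wins[first].start and env.end == wins[last].end

    def test_flat_track_yields_nothing(self):
        assert detect_homozygous_deletion(windows([0.0] * 20)) == []

    def test_single_window_run_flagged_low_confidence(self):
        intervals = detect_homozygous_deletion(windows([0, 0, -2.0, 0, 0]))
        assert len(intervals) == 1
        assert intervals[0].low_confidence
        assert intervals[0].status is CopyStatus.homozygous_loss
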