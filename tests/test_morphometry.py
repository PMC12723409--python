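import numpy as np
import pytest
from skimage.draw import disk, ellipse

from axonsf import (LabelMask, distribution_stats, extract_axon_instances,
                    filter_axon_instances, kde_mode, measure_axon)
from axonsf.morphometry import EmptyDistributionError
from axonsf.protocol import AXON, MYELIN

PX = 0.005  # µm / px


def _annulus_mask(shape, center, r_in, r_out):
    classes = np.zeros(shape, dtype=np.int16)
    rr, cc = disk(center, r_out, shape=shape)
    classes[rr, cc] = MYELIN
    rr, cc = disk(center, r_in, shape=shape)
    classes[rr, cc] = AXON
    return classes


class TestExtractInstances:
    def test_two_disjoint_rings_give_two_candidates(self):
        classes = _annulus_mask((200, 200), (60, 60), 20, 30)
        classes |= _annulus_mask((200, 200), (140, 140), 15, 22)
        cands = extract_axon_instances(LabelMask(classes, PX))
        assert len(cands) == 2
        assert all(c.has_axon and c.has_myelin for c in cands)

    def test_empty_mask_gives_no_candidates(self):
        mask = LabelMask(np.zeros((64, 64), dtype=np.int16), PX)
        assert extract_axon_instances(mask) == []

    def test_shared_myelin_bridge_is_split_by_nearest_axon(self):
        # two axon squares with a continuous myelin band between them:
        # the band's pixels must be assigned by proximity, half to each
        classes = np.zeros((40, 100), dtype=np.int16)
        classes[10:30, 20:80] = MYELIN
        classes[15:25, 25:35] = AXON
        classes[15:25, 65:75] = AXON
        cands = extract_axon_instances(LabelMask(classes, PX))
        assert len(cands) == 2
        m0, m1 = (len(c.myelin_rc[0]) for c in cands)
        total = (classes == MYELIN).sum()
        assert m0 + m1 == total
        assert abs(m0 - m1) / total < 0.1

    def test_orphan_myelin_becomes_axonless_candidate(self):
        classes = _annulus_mask((200, 200), (60, 60), 20, 30)
        rr, cc = disk((150, 150), 12, shape=classes.shape)
        classes[rr, cc] = MYELIN
        cands = extract_axon_instances(LabelMask(classes, PX))
        assert len(cands) == 2
        assert sum(not c.has_axon for c in cands) == 1

    def test_holes_in_axon_blobs_are_filled(self):
        classes = _annulus_mask((120, 120), (60, 60), 20, 30)
        classes[58:62, 58:62] = 0  # puncture the axon
        cands = extract_axon_instances(LabelMask(classes, PX))
        rec = measure_axon(cands[0], PX)
        assert rec.inner_diameter == pytest.approx(40 * PX, rel=0.05)


class TestMeasureAxon:
    def test_digital_disk_diameter(self):
        classes = _annulus_mask((120, 120), (60, 60), 20, 28)
        cand = extract_axon_instances(LabelMask(classes, PX))[0]
        rec = measure_axon(cand, PX)
        assert rec.inner_diameter == pytest.approx(0.20, rel=0.05)
        assert rec.eccentricity < 0.2
        assert rec.myelin_coverage == 1.0

    def test_digital_ellipse_minor_axis(self):
        classes = np.zeros((120, 160), dtype=np.int16)
        rr, cc = ellipse(60, 80, 10, 30, shape=classes.shape)
        classes[rr, cc] = AXON
        rr, cc = ellipse(60, 80, 15, 45, shape=classes.shape)
        classes[rr, cc] = np.where(classes[rr, cc] == AXON, AXON, MYELIN)
        cand = extract_axon_instances(LabelMask(classes, PX))[0]
        rec = measure_axon(cand, PX)
        assert rec.inner_diameter == pytest.approx(20 * PX, rel=0.05)

    def test_annulus_g_ratio(self):
        classes = _annulus_mask((140, 140), (70, 70), 20, 30)
        cand = extract_axon_instances(LabelMask(classes, PX))[0]
        rec = measure_axon(cand, PX)
        assert rec.g == pytest.approx(0.667, abs=0.02)
        assert rec.myelin_thickness == pytest.approx(
            (rec.outer_diameter - rec.inner_diameter) / 2, abs=1e-9)


class TestFilterRules:
    def test_injected_violations_counted_by_reason(self, mask_with_violations):
        mask, truth = mask_with_violations
        cands = extract_axon_instances(mask)
        records, counts = filter_axon_instances(cands, "epon", mask.pixel_size)
        injected = truth.violation.value_counts().to_dict()
        assert counts["accepted"] == injected["clean"]
        assert counts["border"] == injected["border"]
        assert counts["no_myelin"] == injected["unmyelinated"]
        assert counts["eccentricity"] == injected["high_eccentricity"]
        assert counts["coverage"] == injected["low_coverage"]

    def test_conservation_of_candidates(self, mask_with_violations):
        mask, _ = mask_with_violations
        cands = extract_axon_instances(mask)
        _, counts = filter_axon_instances(cands, "epon", mask.pixel_size)
        assert sum(counts.values()) == len(cands)

    def test_tightening_thresholds_never_accepts_more(self, mask_with_violations):
        mask, _ = mask_with_violations
        cands = extract_axon_instances(mask)
        accepted = {}
        for cov in (0.85, 0.95):
            for ecc in (0.975, 0.92):
                _, counts = filter_axon_instances(
                    cands, "epon", mask.pixel_size, thresholds=(cov, ecc))
                accepted[(cov, ecc)] = counts["accepted"]
        assert accepted[(0.95, 0.92)] <= accepted[(0.85, 0.92)] <= accepted[(0.85, 0.975)]
        assert accepted[(0.95, 0.92)] <= accepted[(0.95, 0.975)] <= accepted[(0.85, 0.975)]

    def test_eccentric_blob_straddles_preparation_thresholds(self):
        # eccentricity ~0.96: rejected under the conventional-embedding rules
        # (limit 0.92) but accepted under the cryo rules (limit 0.975)
        classes = np.zeros((240, 240), dtype=np.int16)
        a, b = 60, 17  # ecc = sqrt(1-(17/60)^2) ~ 0.959
        rr, cc = ellipse(120, 120, b, a, shape=classes.shape)
        inner = (rr.copy(), cc.copy())
        rr, cc = ellipse(120, 120, b / 0.7, a / 0.7, shape=classes.shape)
        classes[rr, cc] = MYELIN
        classes[inner] = AXON
        mask = LabelMask(classes, PX)
        cands = extract_axon_instances(mask)
        _, counts_epon = filter_axon_instances(cands, "epon", PX)
        _, counts_cryo = filter_axon_instances(cands, "cryo", PX)
        assert counts_epon["eccentricity"] == 1 and counts_epon["accepted"] == 0
        assert counts_cryo["accepted"] == 1

    def test_round_interior_fiber_accepted_under_both_rule_sets(self):
        classes = _annulus_mask((140, 140), (70, 70), 20, 30)
        mask = LabelMask(classes, PX)
        for prep in ("epon", "cryo"):
            recs, counts = filter_axon_instances(
                extract_axon_instances(mask), prep, PX)
            assert counts["accepted"] == 1 and len(recs) == 1

    def test_unknown_preparation_rejected(self, mask_with_violations):
        mask, _ = mask_with_violations
        with pytest.raises(ValueError):
            filter_axon_instances([], "osmium", mask.pixel_size)


class TestDistributionSummaries:
    def test_kde_mode_of_normal_sample(self, rng):
        x = rng.normal(0.5, 0.1, size=10**5)
        assert kde_mode(x) == pytest.approx(0.5, abs=0.01)

    def test_kde_mode_of_gamma_sample_matches_analytic_mode(self, rng):
        k, theta = 2.0, 0.3
        x = rng.gamma(k, theta, size=10**5)
        assert kde_mode(x) == pytest.approx((k - 1) * theta, rel=0.05)

    def test_degenerate_inputs(self):
        assert kde_mode(np.full(5, 0.3)) == 0.3
        assert kde_mode([0.7]) == 0.7
        with pytest.raises(EmptyDistributionError):
            kde_mode([])

    def test_interpolated_p90(self):
        stats = distribution_stats(np.arange(1.0, 11.0))
        assert stats.p90 == pytest.approx(9.1)

    def test_single_value_stats(self):
        stats = distribution_stats([0.42])
        assert stats.mean == stats.mode == stats.p90 == 0.42
        assert stats.sd == 0.0 and stats.n == 1

    def test_right_skewed_sample_has_p90_above_mode(self, rng):
        x = rng.gamma(3.0, 0.1, size=20000)
        stats = distribution_stats(x)
        assert stats.p90 > stats.mode
        assert stats.mode <= stats.p90 <= x.max()
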