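"""MRW / RNFL / PCT thickness metrics and Garway-Heath sectorization."""

import numpy as np
import pytest

from onhmorph.containers import (
    SECTOR_LIMITS_DEG,
    SECTOR_NAMES,
    CircleScanProfile,
)
from onhmorph.synthetic import simulate_eye
from onhmorph.thickness import (
    compute_mrw,
    compute_pct,
    compute_rnfl_thickness,
    point_to_polyline_distance,
    quality_filter,
    sectorize,
)

from .conftest import HIGH_MYOPIA_SECTORS, make_eye_params


def make_profile(n=360, fobmo=0.0, laterality="OD", rnfl=67.5, pct=109.8, bm_fn=None):
    ang = np.arange(n) * (360.0 / n)
    ilm = np.full(n, 150.0)
    rnfl_arr = ilm + (rnfl(ang) if callable(rnfl) else float(rnfl))
    bm = bm_fn(ang) if bm_fn else np.full(n, 470.0)
    pct_arr = bm + (pct(ang) if callable(pct) else float(pct))
    return CircleScanProfile(
        eye_id="t",
        laterality=laterality,
        fobmo_deg=fobmo,
        angle_deg=ang,
        ilm=ilm,
        rnfl_posterior=rnfl_arr,
        bm_posterior=bm,
        choroid_posterior=pct_arr,
        quality_score_db=25.0,
    )


class TestPolylineDistance:
    def test_perpendicular_foot(self):
        poly = np.array([[-10.0, 0.0], [10.0, 0.0]])
        assert point_to_polyline_distance(np.array([2.0, 5.0]), poly) == pytest.approx(5.0)

    def test_brute_force_oracle_on_curve(self):
        """Distance to a dense sine polyline matches a 1e5-sample brute-force
        minimum to <=0.1 µm."""
        x = np.linspace(-500, 500, 2001)
        poly = np.column_stack([x, 40 * np.sin(x / 80.0)])
        p = np.array([30.0, 120.0])
        xd = np.linspace(-500, 500, 100001)
        brute = np.min(np.hypot(xd - p[0], 40 * np.sin(xd / 80.0) - p[1]))
        assert point_to_polyline_distance(p, poly) == pytest.approx(brute, abs=0.1)


class TestMRW:
    def test_flat_ilm_perpendicular_distance(self):
        scans, _, _ = simulate_eye(make_eye_params(mrw_profile=200.0), seed=0)
        vals, summary = compute_mrw(scans)
        assert np.allclose(vals, 200.0, atol=1e-9)
        assert summary.global_um == pytest.approx(200.0, abs=1e-9)

    def test_shortest_distance_beats_fixed_direction(self):
        """An inclined ILM segment through the same nearest point keeps the
        minimum distance below the vertical (fixed-direction) offset."""
        from onhmorph.thickness import point_to_polyline_distance as d

        p = np.array([0.0, 0.0])
        incl = np.array([[-300.0, -200.0 - 300.0], [300.0, -200.0 + 300.0]])
        vertical_offset = 200.0
        assert d(p, incl) < vertical_offset

    def test_sector_truth_recovery(self, noiseless_eye):
        scans, _, truth = noiseless_eye
        _, summary = compute_mrw(scans)
        for s in SECTOR_NAMES:
            assert summary[s] == pytest.approx(truth.mrw[s], rel=1e-9)
        assert summary.global_um == pytest.approx(truth.mrw.global_um, rel=1e-9)


class TestRNFL:
    def test_constant_profile(self):
        s = compute_rnfl_thickness(make_profile(rnfl=67.5))
        assert s.global_um == pytest.approx(67.5, abs=1e-12)
        for name in SECTOR_NAMES:
            assert s[name] == pytest.approx(67.5, abs=1e-12)

    def test_zero_thickness(self):
        s = compute_rnfl_thickness(make_profile(rnfl=0.0))
        assert s.global_um == 0.0

    def test_double_hump_matches_membership_oracle(self):
        """Sector means of a smooth double-hump profile equal an independent
        per-A-scan membership-and-average oracle."""
        f = lambda a: 60 + 30 * np.sin(np.radians(2 * a)) ** 2
        prof = make_profile(n=768, rnfl=f)
        s = compute_rnfl_thickness(prof)
        ang = prof.angle_deg
        vals = f(ang)
        for name, spans in SECTOR_LIMITS_DEG.items():
            members = np.zeros(ang.shape, dtype=bool)
            for lo, hi in spans:
                members |= (ang >= lo) & (ang < hi)
            assert s[name] == pytest.approx(vals[members].mean(), abs=1e-9)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="segmentation error"):
            make_profile(rnfl=-5.0)


class TestPCT:
    def test_flat_bm_uniform_separation(self):
        s = compute_pct(make_profile(pct=109.8))
        assert s.global_um == pytest.approx(109.8, abs=1e-9)

    def test_zero_choroid(self):
        s = compute_pct(make_profile(pct=0.0))
        assert s.global_um == 0.0

    def test_constant_slope_closed_form(self):
        """BM inclined at constant slope tan(φ)=0.2 with uniform axial
        separation d gives PCT = d·cos(φ) everywhere."""
        r = 1750.0
        bm_fn = lambda a: 300.0 + 0.2 * np.radians(a) * r
        s = compute_pct(make_profile(pct=100.0, bm_fn=bm_fn))
        expected = 100.0 * np.cos(np.arctan(0.2))
        assert s.global_um == pytest.approx(expected, rel=1e-9)

    def test_axial_mode_skips_slope_correction(self):
        r = 1750.0
        bm_fn = lambda a: 300.0 + 0.2 * np.radians(a) * r
        s = compute_pct(make_profile(pct=100.0, bm_fn=bm_fn), mode="axial")
        assert s.global_um == pytest.approx(100.0, abs=1e-9)


class TestSectorize:
    def test_partition_is_complete_and_sums_to_360(self):
        widths = {
            name: sum(hi - lo for lo, hi in spans)
            for name, spans in SECTOR_LIMITS_DEG.items()
        }
        assert widths == {"T": 90, "ST": 40, "SN": 40, "N": 110, "IN": 40, "IT": 40}
        assert sum(widths.values()) == 360

    def test_constant_profile_all_sectors_equal(self):
        ang = np.arange(720) * 0.5
        s = sectorize(np.full(720, 3.25), ang, fobmo_deg=-7.0)
        assert s.global_um == pytest.approx(3.25)
        for name in SECTOR_NAMES:
            assert s[name] == pytest.approx(3.25)

    def test_indicator_profile_brute_force(self):
        """Indicator of [50°, 80°): ST mean 30/40; every other sector mean
        equals its brute-force membership count ratio."""
        ang = np.arange(360) * 1.0
        vals = ((ang >= 50) & (ang < 80)).astype(float)
        s = sectorize(vals, ang, fobmo_deg=0.0)
        assert s["ST"] == pytest.approx(30 / 40)
        for name, spans in SECTOR_LIMITS_DEG.items():
            inside = 0
            width = 0
            for lo, hi in spans:
                inside += np.sum((ang >= max(lo, 50)) & (ang < min(hi, 80)))
                width += np.sum((ang >= lo) & (ang < hi))
            assert s[name] == pytest.approx(inside / width)

    def test_global_is_count_weighted_sector_mean(self):
        rng = np.random.default_rng(1)
        ang = np.arange(768) * (360 / 768)
        vals = rng.uniform(50, 150, 768)
        s = sectorize(vals, ang, fobmo_deg=-7.0)
        counts = {}
        psi = (ang + 7.0) % 360.0
        from onhmorph.thickness import sector_of_angles

        labels = sector_of_angles(psi)
        for name in SECTOR_NAMES:
            counts[name] = np.sum(labels == name)
        weighted = sum(s[n] * counts[n] for n in SECTOR_NAMES) / sum(counts.values())
        assert s.global_um == pytest.approx(weighted, rel=1e-9)

    def test_laterality_mirror_invariance(self):
        """An OD profile and its OS mirror yield identical sector summaries."""
        f = lambda a: 60 + 30 * np.sin(np.radians(a - 70)) ** 2
        od = make_profile(n=768, fobmo=-7.0, rnfl=f)
        os_mirror = CircleScanProfile(
            eye_id="t",
            laterality="OS",
            fobmo_deg=7.0,
            angle_deg=np.sort((180.0 - od.angle_deg) % 360.0),
            ilm=od.ilm[np.argsort((180.0 - od.angle_deg) % 360.0)],
            rnfl_posterior=od.rnfl_posterior[np.argsort((180.0 - od.angle_deg) % 360.0)],
            bm_posterior=od.bm_posterior[np.argsort((180.0 - od.angle_deg) % 360.0)],
            choroid_posterior=od.choroid_posterior[np.argsort((180.0 - od.angle_deg) % 360.0)],
            quality_score_db=25.0,
        )
        s_od = compute_rnfl_thickness(od)
        s_os = compute_rnfl_thickness(os_mirror)
        assert s_os.global_um == pytest.approx(s_od.global_um, rel=1e-9)
        for name in SECTOR_NAMES:
            assert s_os[name] == pytest.approx(s_od[name], rel=1e-9)

    def test_refinement_stability(self):
        """Doubling the A-scan count of a smooth profile moves sector means
        by <= 0.5 µm."""
        f = lambda a: 90 + 25 * np.sin(np.radians(a)) + 10 * np.cos(np.radians(3 * a))
        s1 = compute_rnfl_thickness(make_profile(n=384, rnfl=f))
        s2 = compute_rnfl_thickness(make_profile(n=768, rnfl=f))
        for name in SECTOR_NAMES:
            assert abs(s1[name] - s2[name]) <= 0.5

    def test_empty_sector_raises(self):
        with pytest.raises(ValueError, match="sector"):
            sectorize(np.ones(4), np.array([0.0, 90.0, 180.0, 270.0]), 0.0)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "score,included", [(14.9, False), (15.0, True), (25.0, True)]
    )
    def test_threshold_is_strict_below(self, score, included):
        ok, reason = quality_filter(score)
        assert ok is included
        assert "quality score" in reason

    def test_custom_threshold(self):
        assert quality_filter(20.0, threshold_db=25.0)[0] is False


class TestEndToEndTruth:
    def test_sector_step_profiles_recovered(self, noiseless_eye):
        _, profile, truth = noiseless_eye
        rnfl = compute_rnfl_thickness(profile)
        pct = compute_pct(profile)
        for name in SECTOR_NAMES:
            assert rnfl[name] == pytest.approx(HIGH_MYOPIA_SECTORS["rnfl"][name], abs=1e-6)
            assert pct[name] == pytest.approx(HIGH_MYOPIA_SECTORS["pct"][name], abs=0.2)
        assert rnfl.global_um == pytest.approx(truth.rnfl.global_um, abs=1e-6)
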