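"""Calcium quantification: plaque extraction, lesion length, scoring."""

import itertools

import numpy as np
import pytest

from octcalc.phantom import CALCIUM, PhantomConfig, PlaqueSpec, generate_pullback
from octcalc.quantify import (
    NON_SEVERE,
    SEVERE,
    ScoreRule,
    dichotomize,
    extract_plaques,
    frame_calcium_bins,
    lesion_length,
    oct_calcium_score,
    sample_frames,
    summarize_lesions,
)


def sector_frame(n_s=200, n_a=360, col_lo=30, col_hi=90, row_lo=50, n_rows=100):
    """Label frame with one rectangular (in polar space) calcium sector."""
    lab = np.full((n_s, n_a), 4, dtype=np.uint8)
    cols = np.arange(col_lo, col_hi) % n_a
    lab[row_lo : row_lo + n_rows][:, cols] = CALCIUM
    return lab


class TestExtractPlaques:
    def test_uniform_sector_measures_exactly(self):
        # theta in [30, 90), radial extent 1.0 mm at 0.01 mm/px
        lab = sector_frame()
        (m,) = extract_plaques(lab, radial_res_mm=0.01)
        assert m.arc_deg == pytest.approx(60.0)
        assert m.min_thickness_mm == pytest.approx(1.0)
        assert m.max_thickness_mm == pytest.approx(1.0)
        assert m.angular_span[0] == pytest.approx(30.0)

    def test_wraparound_sector_is_single_plaque(self):
        # Oracle: rotate the mask by 180 degrees and re-measure.
        lab = np.full((64, 360), 4, dtype=np.uint8)
        cols = np.r_[350:360, 0:10]
        lab[10:30][:, cols] = CALCIUM
        (m,) = extract_plaques(lab, radial_res_mm=0.01)
        rotated = np.roll(lab, 180, axis=1)
        (m_rot,) = extract_plaques(rotated, radial_res_mm=0.01)
        assert m.arc_deg == pytest.approx(20.0)
        assert m.arc_deg == pytest.approx(m_rot.arc_deg)
        assert m.min_thickness_mm == pytest.approx(m_rot.min_thickness_mm)

    def test_two_disjoint_sectors_and_full_annulus(self):
        lab = np.full((64, 360), 4, dtype=np.uint8)
        lab[10:20, 40:80] = CALCIUM
        lab[30:40, 200:220] = CALCIUM
        assert len(extract_plaques(lab, 0.01)) == 2
        annulus = np.full((64, 360), 4, dtype=np.uint8)
        annulus[10:20, :] = CALCIUM
        (m,) = extract_plaques(annulus, 0.01)
        assert m.arc_deg == pytest.approx(360.0)

    def test_rotation_equivariance(self, rng):
        lab = sector_frame(col_lo=100, col_hi=230, row_lo=20, n_rows=37)
        (base,) = extract_plaques(lab, 0.01)
        for shift in rng.integers(1, 360, size=5):
            (m,) = extract_plaques(np.roll(lab, int(shift), axis=1), 0.01)
            assert m.arc_deg == pytest.approx(base.arc_deg)
            assert m.min_thickness_mm == pytest.approx(base.min_thickness_mm)
            assert m.max_thickness_mm == pytest.approx(base.max_thickness_mm)

    def test_truncation_flag_when_abutting_shadow(self):
        from octcalc.phantom import GUIDEWIRE_SHADOW

        lab = np.full((64, 360), 4, dtype=np.uint8)
        lab[10:30, 50:70] = CALCIUM
        lab[30:, 50:70] = GUIDEWIRE_SHADOW
        (m,) = extract_plaques(lab, 0.01)
        assert m.truncated
        lab2 = sector_frame()
        (m2,) = extract_plaques(lab2, 0.01)
        assert not m2.truncated

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            extract_plaques(sector_frame(), radial_res_mm=0.0)


class TestLesionLength:
    @staticmethod
    def bins(present, lo=0, hi=90):
        b = np.zeros(360, dtype=bool)
        if present:
            b[lo:hi] = True
        return b

    def test_ten_consecutive_frames_every_frame_mode(self):
        frames = [self.bins(True) for _ in range(10)]
        assert lesion_length(frames, "every_frame", 0.2) == pytest.approx(2.0)

    def test_single_frame_is_one_spacing(self):
        assert lesion_length([self.bins(True)], "every_frame", 0.2) == pytest.approx(0.2)

    def test_non_overlapping_arcs_break_run(self):
        frames = [self.bins(True, 0, 90), self.bins(True, 180, 270), self.bins(True, 180, 270)]
        assert lesion_length(frames, "every_frame", 0.2) == pytest.approx(0.4)

    def test_interval_quadrant_mode_counts_sampled_frames(self):
        # calcium in quadrant 0 on frames 0..10; 1 mm interval at 0.2 mm
        # spacing samples frames 0, 5, 10 -> run of 3 -> 3 mm
        frames = [self.bins(True, 10, 40) for _ in range(11)]
        assert lesion_length(frames, "interval_quadrant", 0.2, 1.0) == pytest.approx(3.0)

    def test_both_modes_are_multiples_of_their_steps(self, rng):
        frames = [self.bins(rng.uniform() < 0.7, 0, int(rng.integers(10, 350))) for _ in range(25)]
        ef = lesion_length(frames, "every_frame", 0.2)
        iq = lesion_length(frames, "interval_quadrant", 0.2, 1.0)
        assert ef / 0.2 == pytest.approx(round(ef / 0.2))
        assert iq / 1.0 == pytest.approx(round(iq / 1.0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            lesion_length([self.bins(True)], "zigzag", 0.2)


class TestScore:
    @pytest.mark.parametrize(
        "thickness,arc,length,expected",
        [
            (0.6, 200.0, 6.0, 4),  # all three criteria exceeded: 1+2+1
            (0.5, 180.0, 5.0, 0),  # equality earns no point (strict >)
            (0.75, 60.0, 2.0, 1),  # thickness only
            (0.4, 200.0, 3.0, 2),  # arc only
            (0.4, 90.0, 6.0, 1),  # length only
        ],
    )
    def test_scoring_rule(self, thickness, arc, length, expected):
        assert oct_calcium_score(thickness, arc, length) == expected

    def test_enumeration_of_all_threshold_combinations(self):
        # Brute force over the 2^3 exceed/not-exceed combinations.
        rule = ScoreRule()
        below = (0.3, 100.0, 2.0)
        above = (0.8, 250.0, 8.0)
        points = (rule.thickness_points, rule.arc_points, rule.length_points)
        for combo in itertools.product([0, 1], repeat=3):
            args = [above[i] if combo[i] else below[i] for i in range(3)]
            expected = sum(p for c, p in zip(combo, points) if c)
            assert oct_calcium_score(*args, rule) == expected

    def test_score_monotone_in_each_input(self):
        grid_t = [0.0, 0.4, 0.5, 0.6, 1.2]
        grid_a = [0.0, 90.0, 180.0, 200.0, 360.0]
        grid_l = [0.0, 3.0, 5.0, 6.0, 12.0]
        for t, a, l in itertools.product(grid_t, grid_a, grid_l):
            s = oct_calcium_score(t, a, l)
            for t2 in grid_t:
                if t2 >= t:
                    assert oct_calcium_score(t2, a, l) >= s
            for a2 in grid_a:
                if a2 >= a:
                    assert oct_calcium_score(t, a2, l) >= s
            for l2 in grid_l:
                if l2 >= l:
                    assert oct_calcium_score(t, a, l2) >= s

    def test_dichotomization(self):
        assert dichotomize(0) == NON_SEVERE
        assert dichotomize(2) == NON_SEVERE
        assert dichotomize(3) == SEVERE
        assert dichotomize(4) == SEVERE
        with pytest.raises(ValueError):
            dichotomize(5)


class TestSampleFrames:
    def test_1mm_interval_at_02mm_spacing_strides_5(self):
        idx = sample_frames(50, 0.2, 1.0)
        np.testing.assert_array_equal(idx, np.arange(0, 50, 5))

    def test_interval_equal_spacing_samples_every_frame(self):
        np.testing.assert_array_equal(sample_frames(7, 0.2, 0.2), np.arange(7))

    def test_counting_oracle_11_frames_stride_5(self):
        assert len(sample_frames(11, 0.2, 1.0)) == 3

    def test_interval_below_spacing_rejected(self):
        with pytest.raises(ValueError):
            sample_frames(10, 0.5, 0.2)


class TestParameterRecovery:
    def test_phantom_measures_recover_generating_spec(self):
        spec = PlaqueSpec("calcium", 90.0, 1.0, start_frame=2, n_frames=5, center_deg=180.0)
        cfg = PhantomConfig(
            n_frames=10,
            n_alines=480,
            n_samples=256,
            lumen_radius_var=0.0,
            plaque_specs=(spec,),
            seed=13,
        )
        _, labels = generate_pullback(cfg)
        lesions, measures = summarize_lesions(
            labels.classes, cfg.radial_res_mm, cfg.frame_spacing_mm
        )
        assert len(lesions) == 1
        lesion = lesions[0]
        assert lesion.max_arc_deg == pytest.approx(90.0, abs=cfg.deg_per_aline)
        assert lesion.max_thickness_mm == pytest.approx(1.0, abs=cfg.radial_res_mm)
        assert lesion.length_mm == pytest.approx(5 * cfg.frame_spacing_mm)
        assert lesion.n_frames == 5
        assert len(measures) == 5
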