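import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virtualqa import features as F
from virtualqa.plans import Beam, ControlPoint
from .conftest import square_control_point, static_square_beam, wrap_plan


def beam_with_cps(cps, n_pairs=20, leaf_width=5.0, total_mu=300.0):
    boundaries = np.arange(n_pairs + 1) * leaf_width - n_pairs * leaf_width / 2
    return Beam(beam_id="B1", energy="6MV", machine_type="Trilogy",
                mlc_model="M120_post2007", leaf_boundaries=boundaries,
                total_mu=total_mu, control_points=cps)


class TestRasterize:
    def test_single_open_pair_area(self):
        # one pair open 10 mm wide, 5 mm leaf width -> 0.5 cm^2
        a = np.zeros(10)
        b = np.zeros(10)
        a[5], b[5] = -5.0, 5.0
        cp = ControlPoint(0, 0.0, a, b, -50, 50, -50, 50)
        boundaries = np.arange(11) * 5.0 - 25.0
        mask = F.rasterize_aperture(cp, boundaries, spacing=0.5)
        assert F.mask_area_cm2(mask) == pytest.approx(0.5, abs=0.05)

    def test_closed_jaws_empty(self):
        cp = square_control_point(20.0)
        object.__setattr__(cp, "jaw_x2", cp.jaw_x1)
        mask = F.rasterize_aperture(cp, np.arange(21) * 5.0 - 50.0)
        assert mask.open_pixels == 0

    def test_leaves_outside_jaws_empty(self):
        cp = square_control_point(20.0, jaw_half=20.0)
        # move the aperture entirely outside the jaw rectangle in x
        a = cp.leaf_positions_bank_a + 100.0
        b = cp.leaf_positions_bank_b + 100.0
        cp2 = ControlPoint(0, 0.0, a, b, -20, 20, -20, 20)
        mask = F.rasterize_aperture(cp2, np.arange(21) * 5.0 - 50.0)
        assert mask.open_pixels == 0


class TestFluence:
    def test_static_aperture_is_binary(self):
        fl = F.accumulate_fluence(static_square_beam(), spacing=1.0)
        assert set(np.unique(fl.values)) <= {0.0, 1.0}
        assert not fl.degenerate

    def test_two_disjoint_apertures_levels(self):
        # aperture A gets 0.75 of MU, disjoint aperture B gets 0.25
        n_pairs, lw = 20, 5.0
        boundaries = np.arange(n_pairs + 1) * lw - n_pairs * lw / 2

        def offset_square(x0, index, mu):
            centers = 0.5 * (boundaries[:-1] + boundaries[1:])
            sel = np.abs(centers) < 15.0
            a = np.where(sel, x0 - 10.0, -40.0)
            b = np.where(sel, x0 + 10.0, -40.0)
            return ControlPoint(index, mu, a, b, -40, 40, -40, 40)

        cps = [offset_square(-25.0, 0, 0.0), offset_square(25.0, 1, 0.75),
               offset_square(25.0, 2, 1.0)]
        fl = F.accumulate_fluence(beam_with_cps(cps), spacing=1.0)
        vals = np.unique(fl.values)
        np.testing.assert_allclose(vals, [0.0, 1 / 3, 1.0], atol=1e-12)

    def test_single_interval_equals_mask(self):
        beam = static_square_beam()
        fl = F.accumulate_fluence(beam, spacing=1.0)
        mask = F.rasterize_aperture(beam.control_points[0],
                                    beam.leaf_boundaries, 1.0,
                                    F._beam_bbox(beam))
        np.testing.assert_array_equal(fl.values > 0, mask.values)

    def test_never_open_flagged_degenerate(self):
        cps = [square_control_point(0.0, 0, 0.0),
               square_control_point(0.0, 1, 1.0)]
        fl = F.accumulate_fluence(beam_with_cps(cps))
        assert fl.degenerate and fl.values.max() == 0


class TestCiao:
    def test_static_square_area(self):
        mask = F.ciao(static_square_beam(half_mm=20.0), spacing=1.0)
        assert F.mask_area_cm2(mask) == pytest.approx(16.0, rel=0.02)

    def test_disjoint_union_adds(self):
        boundaries = np.arange(21) * 5.0 - 50.0
        centers = 0.5 * (boundaries[:-1] + boundaries[1:])
        sel = np.abs(centers) < 10.0

        def sq(x0, idx, mu):
            a = np.where(sel, x0 - 10.0, -40.0)
            b = np.where(sel, x0 + 10.0, -40.0)
            return ControlPoint(idx, mu, a, b, -40, 40, -40, 40)

        beam = beam_with_cps([sq(-25, 0, 0.0), sq(25, 1, 1.0)])
        assert F.mask_area_cm2(F.ciao(beam)) == pytest.approx(8.0, rel=0.02)

    def test_control_point_order_invariance(self):
        beam = beam_with_cps([square_control_point(10, 0, 0.0),
                              square_control_point(20, 1, 0.6),
                              square_control_point(15, 2, 1.0)])
        fwd = F.ciao(beam).values
        rev_cps = [ControlPoint(i, cp.cumulative_mu_fraction,
                                cp.leaf_positions_bank_a,
                                cp.leaf_positions_bank_b, cp.jaw_x1,
                                cp.jaw_x2, cp.jaw_y1, cp.jaw_y2)
                   for i, cp in enumerate([square_control_point(15, 0, 0.0),
                                           square_control_point(20, 1, 0.6),
                                           square_control_point(10, 2, 1.0)])]
        rev = F.ciao(beam_with_cps(rev_cps)).values
        np.testing.assert_array_equal(fwd, rev)


class TestSmallApertureScore:
    def _uniform_gap_beam(self, gap_mm, n_pairs=10):
        boundaries = np.arange(n_pairs + 1) * 5.0 - n_pairs * 5.0 / 2
        a = np.full(n_pairs, -gap_mm / 2)
        b = np.full(n_pairs, gap_mm / 2)
        cps = [ControlPoint(i, float(i), a, b, -40, 40, -40, 40)
               for i in (0, 1)]
        return beam_with_cps(cps, n_pairs=n_pairs)

    def test_uniform_3mm_gaps(self):
        beam = self._uniform_gap_beam(3.0)
        s = F.small_aperture_score(beam, (2, 5, 10, 20))
        assert s == [0.0, 1.0, 1.0, 1.0]

    def test_mixed_gaps_fraction(self):
        n_pairs = 10
        boundaries = np.arange(n_pairs + 1) * 5.0 - 25.0
        gaps = np.array([4.0] * 4 + [30.0] * 6)
        a, b = -gaps / 2, gaps / 2
        cps = [ControlPoint(i, float(i), a, b, -40, 40, -40, 40)
               for i in (0, 1)]
        s = F.small_aperture_score(beam_with_cps(cps, n_pairs=n_pairs), (5.0,))
        assert s[0] == pytest.approx(0.4)

    def test_two_control_points_weighted_mean(self):
        # fractions 0.2 and 0.6 at equal Delta-MU weights -> 0.4
        n_pairs = 10
        gaps1 = np.array([4.0] * 2 + [30.0] * 8)   # fraction 0.2 below 5mm
        gaps2 = np.array([4.0] * 6 + [30.0] * 4)   # fraction 0.6
        cps = [ControlPoint(0, 0.0, -gaps1 / 2, gaps1 / 2, -40, 40, -40, 40),
               ControlPoint(1, 1.0, -gaps2 / 2, gaps2 / 2, -40, 40, -40, 40)]
        s = F.small_aperture_score(beam_with_cps(cps, n_pairs=n_pairs), (5.0,))
        assert s[0] == pytest.approx(0.4)

    def test_no_counted_gaps_is_missing(self):
        beam = self._uniform_gap_beam(0.0)  # everything parked closed
        assert F.small_aperture_score(beam, (5.0,)) == [None]


class TestFluenceLevelFractions:
    def test_uniform_fluence_all_one(self):
        fl = F.accumulate_fluence(static_square_beam())
        fracs = F.fluence_level_fractions(fl, (10, 20, 30, 40, 50))
        assert fracs == [1.0] * 5

    def test_half_area_at_low_level(self):
        grid = np.zeros((10, 10))
        grid[:5] = 1.0
        grid[5:] = 0.3
        fl = F.FluenceGrid((0, 0), 1.0, grid)
        ge50 = F.fluence_level_fractions(fl, (50,))[0]
        assert ge50 == pytest.approx(0.5)

    def test_ten_percent_level_self_normalizes(self):
        fl = F.accumulate_fluence(static_square_beam())
        assert F.fluence_level_fractions(fl, (10,))[0] == 1.0

    def test_degenerate_raises(self):
        fl = F.FluenceGrid((0, 0), 1.0, np.zeros((4, 4)), degenerate=True)
        with pytest.raises(F.DegenerateFluenceError):
            F.fluence_level_fractions(fl, (50,))


class TestShapeMetrics:
    def test_centered_square_inside_radius(self):
        mask = F.ciao(static_square_beam(half_mm=20.0))
        fracs = F.radius_fractions(mask, (5, 10, 20))
        assert fracs == [0.0, 0.0, 0.0]  # half-diagonal 2.83 cm < 5 cm

    def test_square_shape_irregularity(self):
        mask = F.ciao(static_square_beam(half_mm=30.0), spacing=0.5)
        assert F.shape_irregularity(mask) == pytest.approx(4 / np.pi, rel=0.03)

    def test_disc_irregularity_tends_to_one(self):
        def disc_mask(spacing):
            n = int(70 / spacing)
            xs = (np.arange(n) + 0.5) * spacing - 35.0
            X, Y = np.meshgrid(xs, xs)
            return F.ApertureMask((xs[0], xs[0]), spacing,
                                  X ** 2 + Y ** 2 < 30.0 ** 2)

        coarse = abs(F.shape_irregularity(disc_mask(2.0)) - 1.0)
        fine = abs(F.shape_irregularity(disc_mask(0.5)) - 1.0)
        assert fine < 0.02 and fine <= coarse

    def test_perimeter_square(self):
        mask = F.ciao(static_square_beam(half_mm=20.0), spacing=0.5)
        assert F.mask_perimeter_cm(mask) == pytest.approx(16.0, rel=0.03)

    def test_perimeter_additive_over_components(self):
        v = np.zeros((40, 40), dtype=bool)
        v[5:15, 5:15] = True
        v[25:35, 25:35] = True
        two = F.ApertureMask((0, 0), 1.0, v)
        one = F.ApertureMask((0, 0), 1.0, v[:20, :20][:, :])
        p_two = F.mask_perimeter_cm(two)
        v1 = np.zeros((20, 20), dtype=bool)
        v1[5:15, 5:15] = True
        p_one = F.mask_perimeter_cm(F.ApertureMask((0, 0), 1.0, v1))
        assert p_two == pytest.approx(2 * p_one, rel=1e-6)

    def test_disc_perimeter_converges_linearly(self):
        def disc_perimeter(spacing):
            n = int(70 / spacing)
            xs = (np.arange(n) + 0.5) * spacing - 35.0
            X, Y = np.meshgrid(xs, xs)
            m = F.ApertureMask((xs[0], xs[0]), spacing,
                               X ** 2 + Y ** 2 < 30.0 ** 2)
            return F.mask_perimeter_cm(m)

        true = 6 * np.pi
        err2 = abs(disc_perimeter(2.0) - true)
        err05 = abs(disc_perimeter(0.5) - true)
        assert err05 < err2
        assert err05 < 0.01 * true


class TestPenumbra:
    def test_band_fraction_closed_form(self):
        # 100x100 mm aperture, 5 mm margin -> 1 - (90/100)^2 = 0.19
        beam = static_square_beam(half_mm=50.0, n_pairs=24)
        assert F.penumbra_fraction(beam, margin_mm=5.0, spacing=1.0) == \
            pytest.approx(0.19, abs=0.01)

    def test_narrow_aperture_fully_penumbra(self):
        beam = static_square_beam(half_mm=4.0)
        assert F.penumbra_fraction(beam, margin_mm=5.0) == 1.0

    def test_zero_margin_zero_fraction(self):
        beam = static_square_beam(half_mm=20.0)
        assert F.penumbra_fraction(beam, margin_mm=0.0) == 0.0


class TestDutyCycleAndBinning:
    def test_duty_cycle_value(self):
        assert F.duty_cycle(600, 200) == 3.0

    def test_duty_cycle_bin_left_closed(self):
        onehot = F.bin_encode(3.0, (2, 3, 4, 5, 6))
        labels = F.bin_labels("duty_cycle", (2, 3, 4, 5, 6))
        assert labels[int(np.argmax(onehot))] == "duty_cycle_3_4"

    def test_low_duty_first_bin(self):
        onehot = F.bin_encode(F.duty_cycle(100, 200), (2, 3, 4, 5, 6))
        assert onehot[0] == 1.0

    def test_edge_value_goes_right(self):
        onehot = F.bin_encode(5.0, (5, 10))
        assert list(onehot) == [0.0, 1.0, 0.0]

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_indicator_sums_to_one(self, value):
        assert F.bin_encode(value, (2, 3, 4, 5, 6)).sum() == 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            F.bin_encode(float("nan"), (1, 2))


@pytest.fixture(scope="module")
def plan():
    from virtualqa.synthetic import GeneratorConfig, generate_plan
    return generate_plan(GeneratorConfig(seed=9, n_control_points=5,
                                         modulation=0.6), n_beams=2)


class TestAssembly:

    def test_deterministic(self, plan):
        v1 = F.assemble_feature_vector(plan)
        v2 = F.assemble_feature_vector(plan)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_default_length_91(self, plan):
        assert len(F.assemble_feature_vector(plan)) == 91
        assert len(F.DEFAULT_CONFIG.feature_names()) == 91

    def test_one_hot_groups_sum_to_one(self, plan):
        vals = F.assemble_feature_vector(plan).as_dict()
        for group in F.DEFAULT_CONFIG.one_hot_groups():
            assert sum(vals[n] for n in group) == 1.0

    def test_fraction_features_in_unit_interval(self, plan):
        vals = F.assemble_feature_vector(plan).as_dict()
        for name in F.DEFAULT_CONFIG.fraction_feature_names():
            assert 0.0 <= vals[name] <= 1.0, name

    def test_beam_level_needs_plan_context(self, plan):
        with pytest.raises(ValueError):
            F.assemble_feature_vector(plan.beams[0])
        fv = F.assemble_feature_vector(plan.beams[0], plan=plan)
        assert len(fv) == 91

    def test_extract_features_table(self, plan):
        df, failures = F.extract_features([plan], granularity="beam")
        assert len(df) == 2 and not failures
        assert df.columns[0] == "unit_id"

    def test_config_hash_changes_with_config(self):
        assert F.FeatureConfig().config_hash() != \
            F.FeatureConfig(penumbra_margin_mm=6.0).config_hash()
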