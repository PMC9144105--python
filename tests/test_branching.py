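"""Bifurcation analysis: categories, Murray's law, asymmetry, angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coromorph.branching import (
    asymmetry_angle_relation,
    asymmetry_index,
    branch_angle,
    classify_bifurcation,
    extract_bifurcations,
    fit_murray_exponent,
    murray_deviation,
    murray_scatter_comparison,
)
from coromorph.geometry import rotate_deg
from coromorph.simulate import (
    TreeGenParams,
    generate_network,
    sample_bifurcation_diameters,
)

from conftest import make_segment, make_y_network


class _Bif:
    """Minimal stand-in carrying just the fields the statistics read."""

    def __init__(self, m, d1, d2, angle=None, category="dichotomic"):
        self.mother_diam = m
        self.daughter_diams = (max(d1, d2), min(d1, d2))
        self.asymmetry = max(d1, d2) / min(d1, d2)
        self.branch_angle_deg = angle
        self.category = category


class TestAsymmetryIndex:
    @pytest.mark.parametrize("d1,d2,expect", [(150, 100, 1.5), (100, 150, 1.5),
                                              (120, 120, 1.0)])
    def test_examples(self, d1, d2, expect):
        assert asymmetry_index(d1, d2) == pytest.approx(expect)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(0.0, 100.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(d1=st.floats(1, 500), d2=st.floats(1, 500), c=st.floats(0.01, 100))
    def test_order_and_scale_invariance(self, d1, d2, c):
        assert asymmetry_index(d1, d2) == pytest.approx(asymmetry_index(d2, d1))
        assert asymmetry_index(c * d1, c * d2) == pytest.approx(asymmetry_index(d1, d2))


class TestMurrayDeviation:
    def test_exact_symmetric_split(self):
        d = 200.0 / 2 ** (1 / 3)  # both daughters carry half the cube
        assert murray_deviation(200.0, (d, d)) == pytest.approx(0.0, abs=1e-4)

    def test_worked_residual(self):
        # (200^3 - 180^3 - 120^3)/200^3 = (8e6 - 7.56e6)/8e6
        assert murray_deviation(200.0, (180.0, 120.0)) == pytest.approx(0.055, abs=1e-3)

    def test_generalized_exponent_two_pythagorean(self):
        assert murray_deviation(5.0, (3.0, 4.0), exponent=2) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(0.01, 100))
    def test_scale_invariance(self, c):
        r0 = murray_deviation(200.0, (180.0, 120.0))
        assert murray_deviation(c * 200.0, (c * 180.0, c * 120.0)) == pytest.approx(r0)

    def test_missing_diameters_rejected(self):
        with pytest.raises(ValueError):
            murray_deviation(200.0, ())


class TestClassification:
    def test_three_daughters_is_multiplex(self):
        assert classify_bifurcation((10, 40, 60), (150, 120, 90)) == "multiplex"

    def test_dominant_continuing_daughter_is_lateral(self):
        assert classify_bifurcation((5, 70), (200, 90)) == "lateral"

    def test_symmetric_split_is_dichotomic(self):
        assert classify_bifurcation((35, 35), (150, 150)) == "dichotomic"

    def test_stable_under_daughter_reordering(self):
        a = classify_bifurcation((5, 70), (200, 90))
        b = classify_bifurcation((70, 5), (90, 200))
        assert a == b == "lateral"

    def test_too_few_daughters_rejected(self):
        with pytest.raises(ValueError):
            classify_bifurcation((10,), (100,))


class TestBranchAngle:
    def test_perpendicular_daughters(self):
        a = make_segment([(0, 0), (300, 0)], sid=1)
        b = make_segment([(0, 0), (0, 300)], sid=2)
        assert branch_angle(a, b) == pytest.approx(90.0)

    def test_opposite_daughters(self):
        a = make_segment([(0, 0), (300, 0)], sid=1)
        b = make_segment([(0, 0), (-300, 0)], sid=2)
        assert branch_angle(a, b) == pytest.approx(180.0)

    def test_rotation_invariance(self):
        a0 = make_segment([(0, 0), (300, 0)], sid=1)
        b0 = make_segment([(0, 0), (200, 260)], sid=2)
        base = branch_angle(a0, b0)
        a1 = make_segment(rotate_deg(a0.axis, 73.0), sid=1)
        b1 = make_segment(rotate_deg(b0.axis, 73.0), sid=2)
        assert branch_angle(a1, b1) == pytest.approx(base, abs=1e-9)

    def test_extracted_angle_matches_fixture(self, y_network):
        bifs = extract_bifurcations(y_network)
        assert len(bifs) == 1
        assert bifs[0].branch_angle_deg == pytest.approx(60.0, abs=1e-6)
        assert bifs[0].asymmetry == pytest.approx(170 / 120)


class TestMurrayFit:
    def test_noiseless_tree_recovers_exponent_exactly(self):
        net = generate_network(
            TreeGenParams(murray_noise_sd=0.0, tortuosity_amplitude=0.0), seed=3
        )
        bifs = extract_bifurcations(net)
        assert max(abs(b.residual) for b in bifs) < 1e-9
        k, _ = fit_murray_exponent(bifs)
        assert k == pytest.approx(3.0, abs=1e-6)

    def test_exponent_two_tree_recovered(self):
        rng = np.random.default_rng(5)
        df = sample_bifurcation_diameters(200, exponent=2.0, noise_sd=0.0, rng=rng)
        k, _ = fit_murray_exponent(
            [_Bif(*row) for row in df.itertuples(index=False)]
        )
        assert k == pytest.approx(2.0, abs=1e-6)

    def test_noisy_recovery_within_band(self):
        # 5% diameter noise, n=200, asymmetry spanning the observed
        # 1-2.8 range: estimate in [2.7, 3.3] in >=95/100 seeds
        inside = 0
        for rep in range(100):
            rng = np.random.default_rng([77, rep])
            df = sample_bifurcation_diameters(
                200, exponent=3.0, noise_sd=0.05, rng=rng,
                asymmetry_pattern=(1.2, 1.6, 2.0, 2.4, 2.8),
            )
            k, _ = fit_murray_exponent([_Bif(*r) for r in df.itertuples(index=False)])
            inside += 2.7 <= k <= 3.3
        assert inside >= 95

    def test_bootstrap_ci_brackets_truth(self):
        rng = np.random.default_rng(8)
        df = sample_bifurcation_diameters(200, exponent=3.0, noise_sd=0.02, rng=rng)
        k, (lo, hi) = fit_murray_exponent(
            [_Bif(*r) for r in df.itertuples(index=False)], bootstrap=200, seed=1
        )
        assert lo < k < hi
        assert lo < 3.0 < hi

    def test_degenerate_input_rejected(self):
        bifs = [_Bif(200.0, 170.0, 120.0)] * 5
        with pytest.raises(ValueError):
            fit_murray_exponent(bifs)


class TestScatterComparison:
    def _group(self, n, spread, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            m = rng.uniform(150, 400)
            d2 = m / 2 ** (1 / 3)
            res = rng.normal(0, spread)
            # perturb one daughter so the cube-scale residual ~ res
            out.append(_Bif(m, (d2**3 + res) ** (1 / 3), d2))
        return out

    def test_identical_groups_give_f_one(self):
        g = self._group(50, 1e5, seed=1)
        f, p = murray_scatter_comparison(g, g)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_three_fold_spread_detected(self):
        a = self._group(100, 1e5, seed=2)
        b = self._group(100, 3e5, seed=3)
        _, p = murray_scatter_comparison(a, b)
        assert p < 0.01

    def test_single_element_group_rejected(self):
        with pytest.raises(ValueError):
            murray_scatter_comparison(self._group(1, 1e5, 1), self._group(50, 1e5, 2))


class TestAsymmetryAngleRelation:
    def test_exact_linear_relation(self):
        bifs = [
            _Bif(300, 100 * a, 100, angle=30 + 20 * a)
            for a in np.linspace(1.0, 2.5, 20)
        ]
        r, p, slope = asymmetry_angle_relation(bifs)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(20.0)

    def test_permuted_angles_decorrelate(self):
        rng = np.random.default_rng(4)
        a_vals = rng.uniform(1.0, 2.5, 100)
        angles = 30 + 20 * a_vals
        rng.shuffle(angles)
        bifs = [_Bif(300, 100 * a, 100, angle=ang) for a, ang in zip(a_vals, angles)]
        r, _, _ = asymmetry_angle_relation(bifs)
        assert abs(r) < 0.25

    def test_constant_angles_rejected(self):
        bifs = [_Bif(300, 100 * a, 100, angle=45.0) for a in (1.2, 1.5, 1.9)]
        with pytest.raises(ValueError):
            asymmetry_angle_relation(bifs)

    def test_generated_tree_shows_positive_relation(self, baseline_network):
        r, p, slope = asymmetry_angle_relation(extract_bifurcations(baseline_network))
        assert r > 0
        assert slope > 0


def test_lateral_category_on_generated_tree(baseline_network):
    cats = {b.category for b in extract_bifurcations(baseline_network)}
    # strongly asymmetric pattern rungs produce trunk-continuing
    # side-branch nodes classified lateral alongside dichotomic splits
    assert "lateral" in cats and "dichotomic" in cats


def test_multiplex_excluded_from_fit(y_network):
    from coromorph.model import VascularNetwork

    net = make_y_network()
    third = make_segment([(1000.0, 0.0), (1400.0, -500.0)], outer=(100,) * 3,
                         inner=(80,) * 3, sid=4, parent=1)
    net.segments[4] = third
    bifs = extract_bifurcations(net)
    assert bifs[0].category == "multiplex"
    with pytest.raises(ValueError):  # only multiplex left -> nothing to fit
        fit_murray_exponent(bifs)
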