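"""Axis fits, pair detection/classification, spacing and bundle summaries."""

import numpy as np
import pytest

from mtbundle import (
    BundleError,
    PolarityResult,
    RunConfig,
    analyze_particles,
    bundle_summary,
    classify_pair,
    dimer_rise_delta,
    find_pairs,
    fit_axis,
    gap_distance,
    gen_bundle_star,
)
from mtbundle.bundles import BundlePair


def polarity(angle_deg, coherence=1.0):
    return PolarityResult(angle_deg=angle_deg, coherence=coherence,
                          n_used=10, n_flipped=0, confident=coherence >= 0.8)


def line_axis(p0, direction, length, n=20, fid=None):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    ts = np.linspace(0, length, n)
    return fit_axis(np.asarray(p0) + ts[:, None] * d, filament_id=fid)


class TestFitAxis:
    def test_exact_line_has_zero_residual(self):
        x = np.linspace(0, 10, 25)
        model = fit_axis(np.c_[x, 2 * x + 1])
        expect = np.array([1.0, 2.0]) / np.sqrt(5.0)
        np.testing.assert_allclose(np.abs(model.direction @ expect), 1.0, atol=1e-12)
        assert model.residual_nm == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exact_segment(self):
        model = fit_axis([[0.0, 0.0], [3.0, 4.0]])
        assert model.arclength_nm == pytest.approx(5.0)
        assert model.residual_nm == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_residual_matches_noise(self, rng):
        x = np.linspace(0, 500, 50)
        y = 0.3 * x + rng.normal(0, 1.0, 50)
        model = fit_axis(np.c_[x, y])
        assert model.residual_nm == pytest.approx(1.0, rel=0.3)

    def test_coincident_points_error(self):
        with pytest.raises(BundleError):
            fit_axis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])


class TestGapDistance:
    def test_parallel_lines_arithmetic(self):
        a = line_axis((0, 0), (1, 0), 300)
        b = line_axis((0, 28.785), (1, 0), 300)
        center, edge = gap_distance(a, b, outer_diameter_nm=25.0)
        assert center == pytest.approx(28.785, abs=1e-9)
        assert edge == pytest.approx(3.785, abs=1e-9)

    def test_identical_axes_give_negative_edge_gap(self):
        a = line_axis((0, 0), (1, 0), 100)
        center, edge = gap_distance(a, a, outer_diameter_nm=25.0)
        assert center == pytest.approx(0.0, abs=1e-9)
        assert edge == pytest.approx(-25.0, abs=1e-9)

    def test_converging_lines_mean_matches_fine_integration(self):
        a = line_axis((0, 0), (1, 0), 200, n=40)
        b = fit_axis(np.c_[np.linspace(0, 200, 40),
                           30.0 - 0.02 * np.linspace(0, 200, 40)])
        center, _ = gap_distance(a, b, n_samples=64)
        xs = np.linspace(0, 200, 20001)
        theta = np.arctan(0.02)
        oracle = np.mean(np.abs(np.cos(theta) * (30.0 - 0.02 * xs)))
        assert center == pytest.approx(oracle, rel=1e-3)

    def test_symmetry(self):
        a = line_axis((0, 0), (1, 0.05), 250)
        b = line_axis((10, 30), (1, 0), 200)
        ab = gap_distance(a, b)
        ba = gap_distance(b, a)
        assert ab[0] == pytest.approx(ba[0], rel=1e-6)

    def test_disjoint_axes_error(self):
        a = line_axis((0, 0), (1, 0), 50)
        b = line_axis((500, 10), (1, 0), 50)
        with pytest.raises(BundleError):
            gap_distance(a, b)


class TestFindPairs:
    def test_close_parallel_axes_pair_once(self):
        a = line_axis((0, 0), (1, 0), 300, fid=("m", 1))
        b = line_axis((0, 30), (1, 0), 300, fid=("m", 2))
        pairs = find_pairs([a, b])
        assert len(pairs) == 1
        assert pairs[0].edge_gap_nm == pytest.approx(5.0, abs=1e-9)

    def test_distant_axes_do_not_pair(self):
        a = line_axis((0, 0), (1, 0), 300, fid=("m", 1))
        b = line_axis((0, 200), (1, 0), 300, fid=("m", 2))
        assert find_pairs([a, b]) == []

    def test_three_mutually_close_axes_give_all_pairs(self):
        axes = [line_axis((0, 30 * k), (1, 0), 300, fid=("m", k)) for k in range(3)]
        pairs = find_pairs(axes)
        ids = {(p.id_a, p.id_b) for p in pairs}
        assert len(pairs) == 3 == len(ids)   # C(3,2), no duplicates

    def test_non_confident_polarity_excludes_pair(self):
        a = line_axis((0, 0), (1, 0), 300, fid=("m", 1))
        b = line_axis((0, 30), (1, 0), 300, fid=("m", 2))
        pols = {("m", 1): polarity(0.0), ("m", 2): polarity(5.0, coherence=0.2)}
        assert find_pairs([a, b], pols) == []


class TestClassifyPair:
    @pytest.mark.parametrize("a1,a2,cls,angle", [
        (0.0, 11.5, "parallel", 11.5),
        (0.0, 180.0, "antiparallel", 180.0),
        (0.0, 90.0, "ambiguous", 90.0),
    ])
    def test_classes(self, a1, a2, cls, angle):
        got_cls, got_angle = classify_pair(polarity(a1), polarity(a2))
        assert got_cls == cls
        assert got_angle == pytest.approx(angle, abs=1e-6)

    def test_symmetric(self):
        p1, p2 = polarity(20.0), polarity(140.0)
        assert classify_pair(p1, p2) == classify_pair(p2, p1)


class TestBundleSummary:
    def test_counts_and_fraction(self):
        pairs = ([BundlePair(("m", 1), ("m", 2), "parallel", 10.0, 30.0, 5.0, 1.0)] * 91
                 + [BundlePair(("m", 1), ("m", 2), "antiparallel", 170.0, 30.0, 5.0, 1.0)] * 86)
        s = bundle_summary(pairs)
        assert s.n_total == 177 and s.n_parallel == 91 and s.n_antiparallel == 86
        assert s.fraction_parallel == pytest.approx(91 / 177)
        assert s.n_total == s.n_parallel + s.n_antiparallel + s.n_ambiguous

    def test_exact_binomial_p(self):
        pairs = [BundlePair(("m", 1), ("m", 2), "parallel", 10.0, 30.0, 5.0, 1.0)] * 10
        s = bundle_summary(pairs)
        assert s.binomial_p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_empty_input_error(self):
        with pytest.raises(BundleError):
            bundle_summary([])


class TestDimerRise:
    def test_printed_operands(self):
        cmp = dimer_rise_delta(83.96, 82.25)
        assert cmp.delta_A == pytest.approx(1.71)
        assert cmp.delta_display == "1.7"

    def test_zero_and_negative_delta(self):
        assert dimer_rise_delta(80.0, 80.0).delta_A == 0.0
        assert dimer_rise_delta(80.0, 83.0).delta_A == pytest.approx(-3.0)

    def test_non_positive_rise_error(self):
        with pytest.raises(BundleError):
            dimer_rise_delta(0.0, 82.25)


class TestPipelineGroundTruth:
    def test_zero_noise_recovery_is_exact(self):
        table, truth = gen_bundle_star(n_pairs=20, angle_noise_deg=0.0,
                                       coord_noise_nm=0.0, seed=10)
        _, pairs, summary = analyze_particles(table)
        assert summary.n_total == 20
        by_mic = {e["micrograph_id"]: e for e in truth.entities}
        for p in pairs:
            e = by_mic[p.id_a[0]]
            want = "parallel" if e["parallel"] else "antiparallel"
            assert p.orientation_class == want
            assert p.edge_gap_nm == pytest.approx(e["edge_gap_nm"], abs=1e-6)

    def test_moderate_noise_classes_all_correct_and_gaps_close(self):
        table, truth = gen_bundle_star(n_pairs=40, angle_noise_deg=10.0,
                                       coord_noise_nm=1.0, seed=11)
        _, pairs, summary = analyze_particles(table)
        assert summary.n_total == 40
        by_mic = {e["micrograph_id"]: e for e in truth.entities}
        errs = []
        for p in pairs:
            e = by_mic[p.id_a[0]]
            want = "parallel" if e["parallel"] else "antiparallel"
            assert p.orientation_class == want
            errs.append(p.edge_gap_nm - e["edge_gap_nm"])
        assert np.sqrt(np.mean(np.square(errs))) <= 2.0   # 2x coord noise

    def test_global_polarity_flip_leaves_summary_unchanged(self):
        table, _ = gen_bundle_star(n_pairs=15, seed=12)
        _, _, base = analyze_particles(table)
        flipped = table
        flipped.df = flipped.df.copy()
        from mtbundle import wrap_angle_deg
        flipped.df["psi_deg"] = wrap_angle_deg(flipped.df["psi_deg"] + 180.0)
        _, _, after = analyze_particles(flipped)
        assert after.n_parallel == base.n_parallel
        assert after.n_antiparallel == base.n_antiparallel
        assert after.gap_mean_nm == pytest.approx(base.gap_mean_nm, rel=1e-9)
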