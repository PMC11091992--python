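"""The packaged count table and the synthetic trial/cohort/rater generators."""

import numpy as np
import pytest

from imckit import (
    PATTERN_ORDER,
    CohortSpec,
    CurveSpec,
    RaterSimSpec,
    ValidationError,
    build_contingency,
    cohen_kappa,
    generate_cohort,
    generate_repetition,
    generate_trial,
    simulate_raters,
    study_labels,
)
from imckit.synthetic import identity_confusion, uniform_confusion


class TestStudyCounts:
    def test_cell_values(self, counts):
        assert counts.at["Valley", "PFJ"] == 10
        assert counts.at["Normal", "Healthy"] == 35
        assert counts.at["Drop", "ACL+MS"] == 8

    def test_group_sizes_and_totals(self, counts):
        assert list(counts.sum(axis=0)) == [10, 17, 24, 23, 40]
        assert list(counts.sum(axis=1)) == [48, 21, 14, 31]
        assert counts.to_numpy().sum() == 114

    def test_expanded_labels_roundtrip(self, counts):
        labels = study_labels()
        assert len(labels) == 114
        assert build_contingency(labels).equals(counts)


class TestCurveGeneration:
    def test_determinism_bitwise(self):
        spec = CurveSpec(pattern="Valley", noise_sd=0.05, seed=11)
        a = generate_repetition(spec, 1, seed=42)
        b = generate_repetition(spec, 1, seed=42)
        assert np.array_equal(a.torque, b.torque)
        assert np.array_equal(a.velocity, b.velocity)

    def test_noiseless_repetitions_identical(self):
        spec = CurveSpec(pattern="Drop", noise_sd=0.0, seed=0)
        a = generate_repetition(spec, 1, seed=1)
        b = generate_repetition(spec, 2, seed=99)
        assert np.allclose(a.torque, b.torque)  # noise-free: seed irrelevant

    def test_angle_range_and_orientation(self):
        rep = generate_repetition(CurveSpec(), 1, seed=0)
        assert rep.angle[0] == pytest.approx(90.0)
        assert rep.angle[-1] == pytest.approx(10.0)
        assert (np.diff(rep.angle) < 0).all()  # extension: flexion decreases

    def test_velocity_trapezoid(self):
        spec = CurveSpec()
        rep = generate_repetition(spec, 1, seed=0)
        speed = np.abs(rep.velocity)
        assert speed.max() == pytest.approx(60.0)
        ramp = (90.0 - rep.angle < spec.ramp_deg) | (rep.angle - 10.0 < spec.ramp_deg)
        assert (speed[ramp] < 60.0).all()
        assert np.allclose(speed[~ramp], 60.0)
        # sub-plateau samples exist at both ends of the movement
        assert (speed < 50.0).any()

    def test_valley_notch_depth_matches_kernel(self):
        """At the notch centre the normalized torque falls ~notch_depth
        below the parabolic base evaluated there (closed-form check)."""
        spec = CurveSpec(pattern="Valley", noise_sd=0.0)
        rep = generate_repetition(spec, 1, seed=0)
        norm = rep.torque / rep.torque.max()
        center = spec.peak_angle + spec.notch_offset
        width = max(90.0 - spec.peak_angle, spec.peak_angle - 10.0)
        base_at_center = 1.0 - ((center - spec.peak_angle) / width) ** 2
        window = np.abs(rep.angle - center) <= 1.0
        expected = base_at_center - spec.notch_depth
        assert norm[window].min() == pytest.approx(expected, abs=5e-3)

    def test_drop_step_depth_matches_kernel(self):
        spec = CurveSpec(pattern="Drop", noise_sd=0.0)
        rep = generate_repetition(spec, 1, seed=0)
        norm = rep.torque / rep.torque.max()
        width = max(90.0 - spec.peak_angle, spec.peak_angle - 10.0)
        # far past the step the curve sits drop_depth below the base
        probe = np.abs(rep.angle - 35.0) <= 0.5
        base = 1.0 - ((rep.angle[probe] - spec.peak_angle) / width) ** 2
        assert np.allclose(norm[probe], base - spec.drop_depth, atol=5e-3)

    def test_trial_repetition_counts(self):
        assert len(generate_trial(CurveSpec())) == 5
        assert len(generate_trial(CurveSpec(n_repetitions=3))) == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"peak_torque": -5.0},
            {"peak_angle": 5.0},
            {"peak_angle": 95.0},
            {"rom": (10.0, 90.0)},
            {"noise_sd": -0.1},
            {"pattern": "Wiggle"},
            {"n_repetitions": 0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises((ValidationError, ValueError)):
            CurveSpec(**kwargs)


class TestCohort:
    def test_default_cohort_reproduces_table(self, counts):
        trials = generate_cohort(CohortSpec(seed=0))
        assert len(trials) == 114
        injected = build_contingency(
            [(t.injected_pattern, t.injury_class) for t in trials]
        )
        assert injected.equals(counts)

    def test_single_trial_cohort(self):
        dist = {"Healthy": {"Normal": 1}}
        trials = generate_cohort(CohortSpec(pattern_distribution=dist, seed=0))
        assert len(trials) == 1
        assert trials[0].injury_class == "Healthy"
        assert trials[0].injected_pattern == "Normal"
        assert len(trials[0].repetitions) == 5

    def test_cohort_determinism(self):
        dist = {"ACL": {"Drop": 2}, "Healthy": {"Normal": 1}}
        a = generate_cohort(CohortSpec(pattern_distribution=dist, seed=9))
        b = generate_cohort(CohortSpec(pattern_distribution=dist, seed=9))
        for ta, tb in zip(a, b):
            for ra, rb in zip(ta.repetitions, tb.repetitions):
                assert np.array_equal(ra.torque, rb.torque)

    def test_inconsistent_class_counts_rejected(self):
        spec = CohortSpec(class_counts={"ACL": 3})  # table column sums to 10
        with pytest.raises(ValidationError):
            spec.distribution()


class TestRaterSimulation:
    def test_identity_raters_reproduce_truth(self):
        truth = ["Valley", "Normal", "Drop", "Shaking"] * 5
        a, b = simulate_raters(
            truth,
            RaterSimSpec(identity_confusion(), seed=1),
            RaterSimSpec(identity_confusion(), seed=2),
        )
        assert a == truth
        assert b == truth

    def test_seeded_reproducibility(self):
        truth = ["Normal", "Valley"] * 10
        spec_a = RaterSimSpec(uniform_confusion(), seed=7)
        spec_b = RaterSimSpec(uniform_confusion(), seed=8)
        first = simulate_raters(truth, spec_a, spec_b)
        second = simulate_raters(truth, spec_a, spec_b)
        assert first == second

    def test_non_stochastic_rows_rejected(self):
        bad = {p: {p: 0.5} for p in PATTERN_ORDER}
        with pytest.raises(ValidationError):
            simulate_raters(["Normal"], RaterSimSpec(bad), RaterSimSpec(identity_confusion()))

    def test_independent_raters_yield_null_kappa(self):
        rng = np.random.default_rng(0)
        truth = list(rng.choice(list(PATTERN_ORDER), size=10_000))
        a, b = simulate_raters(
            truth,
            RaterSimSpec(identity_confusion(), seed=21),
            RaterSimSpec(uniform_confusion(), seed=22),
        )
        assert abs(cohen_kappa(a, b).kappa) < 0.03
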