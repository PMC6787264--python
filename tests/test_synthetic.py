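"""Generator determinism, invariants, limits and calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from walkmem import (
    BoundaryCategory,
    Group,
    GroupParams,
    default_group_params,
    make_walk_schema,
    sample_mallows,
    simulate_cohort,
)
from walkmem.segmentation import (
    build_prototypes,
    normalize_boundaries,
    temporal_accuracy_score,
    typicality_score,
)
from walkmem.synthetic import (
    Transition,
    WalkSchema,
    simulate_participant_boundaries,
    simulate_recall_cohort,
    simulate_segmentation_cohort,
    simulate_toj_cohort,
)
from walkmem.types import ValidationError


class TestWalkSchema:
    def test_deterministic_given_seed(self):
        assert make_walk_schema(35, seed=1) == make_walk_schema(35, seed=1)

    def test_positions_strictly_increasing_in_unit_interval(self):
        schema = make_walk_schema(35, seed=1)
        pos = [t.position for t in schema.transitions]
        assert all(0 <= p < 1 for p in pos)
        assert all(b > a for a, b in zip(pos, pos[1:]))
        assert len(pos) == 35

    def test_too_few_transitions_rejected(self):
        with pytest.raises(ValidationError):
            make_walk_schema(10, seed=1)

    def test_perceptual_majority_within_binomial_band(self):
        """Expected 0.6 * 35 = 21 perceptual transitions; the count over
        many seeds stays inside the aggregate binomial 99% interval."""
        counts = [
            sum(
                t.category == BoundaryCategory.PERCEPTUAL
                for t in make_walk_schema(35, seed=s).transitions
            )
            for s in range(200)
        ]
        total = sum(counts)
        n = 200 * 35
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.6)
        assert lo <= total <= hi


def noise_free_schema(k=30):
    """Evenly spaced, maximally salient transitions (spacing > 2w so no
    two transitions ever share a matching window)."""
    return WalkSchema(
        transitions=tuple(
            Transition(
                position=(i + 0.5) / k,
                salience=1.0,
                category=BoundaryCategory.PERCEPTUAL,
            )
            for i in range(k)
        ),
        n_pictures=360,
    )


class TestSegmentationGenerator:
    def test_noise_free_limit(self):
        """jitter 0, detection 1, no spurious presses: every participant
        reproduces the reference exactly — temporal accuracy 0 and
        typicality equal to the reference size."""
        schema = noise_free_schema()
        params = GroupParams(
            detection_rate=1.0,
            jitter_sd=0.0,
            extra_press_rate=0.0,
            rater_disagreement=0.0,
        )
        rng = np.random.default_rng(0)
        reference = {
            f"r{i}": normalize_boundaries(
                simulate_participant_boundaries(schema, params, 360, rng, f"r{i}"),
                360,
            )
            for i in range(12)
        }
        prototypes = build_prototypes(reference, w=0.02, top_k=30)
        for i in range(5):
            nb = normalize_boundaries(
                simulate_participant_boundaries(schema, params, 360, rng, f"p{i}"),
                360,
            )
            assert typicality_score(nb, prototypes, w=0.02) == 12.0
            assert temporal_accuracy_score(nb, prototypes, w=0.02) == 0.0

    def test_mean_accuracy_increases_with_jitter(self):
        schema = noise_free_schema()
        rng = np.random.default_rng(7)
        reference = {
            f"r{i}": normalize_boundaries(
                simulate_participant_boundaries(
                    schema,
                    GroupParams(jitter_sd=0.003, extra_press_rate=0.0),
                    360,
                    rng,
                    f"r{i}",
                ),
                360,
            )
            for i in range(12)
        }
        prototypes = build_prototypes(reference, w=0.02, top_k=30)

        def mean_accuracy(jitter, seed):
            r = np.random.default_rng(seed)
            vals = []
            for i in range(50):
                nb = normalize_boundaries(
                    simulate_participant_boundaries(
                        schema,
                        GroupParams(jitter_sd=jitter, extra_press_rate=0.0),
                        360,
                        r,
                        f"p{i}",
                    ),
                    360,
                )
                vals.append(temporal_accuracy_score(nb, prototypes, w=0.02))
            return float(np.nanmean(vals))

        assert mean_accuracy(0.010, 21) > mean_accuracy(0.005, 21)

    def test_spurious_presses_lower_typicality(self):
        schema = noise_free_schema()
        rng = np.random.default_rng(3)
        reference = {
            f"r{i}": normalize_boundaries(
                simulate_participant_boundaries(
                    schema,
                    GroupParams(jitter_sd=0.003, extra_press_rate=0.0),
                    360,
                    rng,
                    f"r{i}",
                ),
                360,
            )
            for i in range(12)
        }
        prototypes = build_prototypes(reference, w=0.02, top_k=30)

        def mean_typicality(extra, seed):
            r = np.random.default_rng(seed)
            vals = []
            for i in range(50):
                nb = normalize_boundaries(
                    simulate_participant_boundaries(
                        schema,
                        GroupParams(jitter_sd=0.003, extra_press_rate=extra),
                        360,
                        r,
                        f"p{i}",
                    ),
                    360,
                )
                vals.append(typicality_score(nb, prototypes, w=0.02))
            return float(np.mean(vals))

        assert mean_typicality(3.0, 22) < mean_typicality(0.0, 22)

    def test_presses_sorted_unique_and_in_range(self, small_sim):
        for pid, recs in small_sim.cohort.boundaries.items():
            total = small_sim.cohort.participants[pid].total_pictures
            idx = [r.picture_index for r in recs]
            assert idx == sorted(set(idx))
            assert all(0 <= i < total for i in idx)


class TestMallows:
    def test_large_theta_concentrates_on_identity(self, rng):
        for L in (5, 12):
            assert sample_mallows(rng, L, 50.0) == tuple(range(1, L + 1))

    def test_theta_monotonically_sharpens_ordering(self):
        """Larger concentration gives smaller mean displacement."""
        from walkmem.ordering import deviation_score
        from walkmem.types import OrderingResponse, Task

        means = []
        for theta in (0.0, 0.5, 1.0, 2.0):
            rng = np.random.default_rng(40)
            vals = []
            for i in range(300):
                resp = OrderingResponse(
                    "p", Task.PICTURE_SERIES, f"s{i}",
                    sample_mallows(rng, 12, theta),
                )
                vals.append(deviation_score([resp], n_series=1, series_length=12))
            means.append(np.mean(vals))
        assert means == sorted(means, reverse=True)


class TestCountModels:
    def test_recall_means_match_calibration_targets(self):
        """At n=2000 per group the sample item-count means land within
        ±0.5 of the calibrated group means."""
        params = default_group_params()
        for group, target in ((Group.PATIENT, 25.17), (Group.CONTROL, 31.11)):
            by_pid = {f"x{i:04d}": params[group] for i in range(2000)}
            recalls = simulate_recall_cohort(by_pid, seed=13)
            means = np.mean([len(r.checklist_items) for r in recalls.values()])
            assert abs(means - target) < 0.5

    def test_zero_component_probability_gives_zero_prevalence(self):
        from walkmem import component_prevalence

        params = GroupParams(
            component_probs={"action_with_interaction": 0.0, "spatial_movement": 0.9}
        )
        recalls = simulate_recall_cohort({"p1": params, "p2": params}, seed=1)
        for coding in recalls.values():
            prev = component_prevalence(list(coding.units))
            assert prev["action_with_interaction"] == 0.0

    def test_toj_binomial_mean(self):
        params = GroupParams(toj_error_rate_100=0.07, toj_error_rate_500=0.02)
        by_pid = {f"x{i:04d}": params for i in range(5000)}
        records = simulate_toj_cohort(by_pid, seed=2)
        props = [r.n_errors / r.n_trials for r in records if r.soa_ms == 100]
        assert abs(np.mean(props) - 0.07) < 0.005

    def test_toj_zero_rate_never_errs(self):
        params = GroupParams(toj_error_rate_100=0.0, toj_error_rate_500=0.0)
        records = simulate_toj_cohort({"p1": params}, seed=3)
        assert all(r.n_errors == 0 for r in records)


class TestDeterminism:
    def test_identical_seeds_give_identical_cohorts(self):
        a = simulate_cohort(seed=42, n_patients=4, n_controls=4, n_reference=4)
        b = simulate_cohort(seed=42, n_patients=4, n_controls=4, n_reference=4)
        assert a.cohort.participants == b.cohort.participants
        assert a.cohort.boundaries == b.cohort.boundaries
        assert a.cohort.orderings == b.cohort.orderings
        assert a.cohort.recalls == b.cohort.recalls
        assert a.cohort.toj == b.cohort.toj
        assert a.schema == b.schema

    def test_different_seeds_differ(self):
        a = simulate_cohort(seed=1, n_patients=4, n_controls=4, n_reference=4)
        b = simulate_cohort(seed=2, n_patients=4, n_controls=4, n_reference=4)
        assert a.cohort.boundaries != b.cohort.boundaries
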