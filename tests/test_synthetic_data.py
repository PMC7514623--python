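import numpy as np
import pytest
from scipy.stats import spearmanr

from flucto.io_preproc import (
    INC,
    PreprocConfig,
    Site,
    compute_ac_updrs,
    pair_rounds,
    segment_windows,
    severity_label,
)
from flucto.symptom_features import average_jerk, band_power
from flucto.synthetic_data import (
    CohortSpec,
    SeverityProfile,
    generate_cohort,
    generate_subject,
    simulate_recording,
)


class TestSeverityProfile:
    def test_pseudo_updrs_monotone_in_both_levels(self):
        base = SeverityProfile(0.3, 0.3).pseudo_updrs
        assert SeverityProfile(0.5, 0.3).pseudo_updrs > base
        assert SeverityProfile(0.3, 0.5).pseudo_updrs > base
        assert SeverityProfile(0.0, 0.0).pseudo_updrs >= 0

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            SeverityProfile(1.2, 0.0)


class TestSimulateRecording:
    def test_deterministic_given_seed(self):
        p = SeverityProfile(0.5, 0.5)
        a = simulate_recording(p, 20.0, seed=3)
        b = simulate_recording(p, 20.0, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_no_tremor_keeps_band_near_background(self):
        cfg = PreprocConfig()
        quiet = simulate_recording(SeverityProfile(0.0, 0.5), 40.0, seed=1)
        loud = simulate_recording(SeverityProfile(1.0, 0.5), 40.0, seed=1)

        def mean_band(rec):
            wins = segment_windows(rec, cfg)
            return np.mean(
                [
                    sum(band_power(w[:, ax], rec.fs, 4, 6) for ax in range(3))
                    for w in wins
                ]
            )

        assert mean_band(loud) > 10 * mean_band(quiet)

    def test_tremor_power_strictly_increasing_over_levels(self):
        cfg = PreprocConfig()
        levels = np.linspace(0.1, 1.0, 10)
        means = []
        for level in levels:
            rec = simulate_recording(
                SeverityProfile(float(level), 0.4), 30.0, seed=17
            )
            wins = segment_windows(rec, cfg)
            means.append(
                np.mean(
                    [
                        sum(band_power(w[:, ax], rec.fs, 4, 6) for ax in range(3))
                        for w in wins
                    ]
                )
            )
        rho, _ = spearmanr(levels, means)
        assert rho == pytest.approx(1.0)

    def test_bradykinesia_suppresses_low_band_and_jerk(self):
        cfg = PreprocConfig()
        levels = np.linspace(0.0, 1.0, 10)
        band, jerk = [], []
        for level in levels:
            rec = simulate_recording(
                SeverityProfile(0.3, float(level)), 30.0, seed=23
            )
            wins = segment_windows(rec, cfg)
            band.append(
                np.mean(
                    [
                        sum(band_power(w[:, ax], rec.fs, 1, 4) for ax in range(3))
                        for w in wins
                    ]
                )
            )
            jerk.append(
                np.mean(
                    [
                        sum(average_jerk(w[:, ax], rec.fs) for ax in range(3))
                        for w in wins
                    ]
                )
            )
        assert spearmanr(levels, band)[0] < -0.8
        assert spearmanr(levels, jerk)[0] < -0.8

    def test_ankle_tremor_damped(self):
        p = SeverityProfile(1.0, 0.2)
        cfg = PreprocConfig()

        def band_mean(site):
            rec = simulate_recording(p, 30.0, seed=4, site=site)
            wins = segment_windows(rec, cfg)
            return np.mean(
                [
                    sum(band_power(w[:, ax], rec.fs, 4, 6) for ax in range(3))
                    for w in wins
                ]
            )

        assert band_mean(Site.ANKLE) < 0.5 * band_mean(Site.WRIST)


class TestGenerateSubject:
    def test_identical_profiles_give_minimal_labels(self):
        p = SeverityProfile(0.6, 0.6)
        sub = generate_subject(p, p, n_rounds=4, seed=0, round_duration_s=10.0)
        for pair in pair_rounds(sub.rounds):
            assert abs(pair.delta_updrs) <= 1
            assert pair.severity_label == 0
        assert sub.true_severity == 0

    def test_large_change_lands_in_severe_class(self):
        # OFF score 33, ON score 10
        off = SeverityProfile(0.6, 0.43)
        on = SeverityProfile(0.1, 0.08)
        assert off.pseudo_updrs == 33
        assert on.pseudo_updrs == 10
        sub = generate_subject(off, on, n_rounds=4, seed=1, round_duration_s=10.0)
        assert severity_label(sub.ac_updrs) == 3 == sub.true_severity

    def test_scores_monotone_along_schedule(self):
        off = SeverityProfile(0.8, 0.7)
        on = SeverityProfile(0.2, 0.2)
        for schedule in ("step", "linear"):
            sub = generate_subject(
                off, on, n_rounds=4, seed=2, schedule=schedule,
                round_duration_s=10.0,
            )
            scores = [r.updrs_iii for r in sub.rounds]
            assert scores == sorted(scores, reverse=True)

    def test_seed_changes_signals_not_scores(self):
        off, on = SeverityProfile(0.8, 0.7), SeverityProfile(0.3, 0.3)
        a = generate_subject(off, on, 3, seed=1, round_duration_s=10.0)
        b = generate_subject(off, on, 3, seed=2, round_duration_s=10.0)
        assert [r.updrs_iii for r in a.rounds] == [r.updrs_iii for r in b.rounds]
        assert not np.array_equal(
            a.rounds[0].recordings[Site.WRIST].samples,
            b.rounds[0].recordings[Site.WRIST].samples,
        )

    def test_non_converting_subject_is_inconclusive(self):
        off = SeverityProfile(0.8, 0.7)
        sub = generate_subject(off, None, 3, seed=5, round_duration_s=10.0)
        assert all(r.state == "off" for r in sub.rounds)
        assert sub.true_severity is INC
        assert compute_ac_updrs(
            [r.updrs_iii for r in sub.rounds if r.state == "off"], []
        ) is INC

    def test_timeline_contains_scored_rounds(self):
        off, on = SeverityProfile(0.8, 0.7), SeverityProfile(0.3, 0.3)
        sub = generate_subject(
            off, on, 4, seed=3, round_duration_s=10.0, n_timeline_rounds=10
        )
        assert len(sub.timeline_rounds) == 10
        assert len(sub.rounds) == 4
        timeline_ids = {r.round_id for r in sub.timeline_rounds}
        assert {r.round_id for r in sub.rounds} <= timeline_ids
        scored = [r for r in sub.timeline_rounds if r.updrs_iii is not None]
        assert len(scored) == 4

    def test_bad_round_counts_rejected(self):
        p = SeverityProfile(0.5, 0.5)
        with pytest.raises(ValueError):
            generate_subject(p, p, 1, seed=0)
        with pytest.raises(ValueError):
            generate_subject(p, p, 4, seed=0, n_timeline_rounds=2)


class TestGenerateCohort:
    SPEC = CohortSpec(
        n_per_class=(1, 2, 1, 2),
        n_inconclusive=1,
        rounds_range=(3, 4),
        timeline_rounds_range=(4, 5),
        round_duration_s=10.0,
        seed=42,
    )

    def test_class_counts_match_spec(self):
        cohort = generate_cohort(self.SPEC)
        counts = cohort.class_counts
        assert counts[0] == 1 and counts[1] == 2 and counts[2] == 1
        assert counts[3] == 2 and counts[INC] == 1

    def test_study_style_composition(self):
        spec = CohortSpec(
            n_per_class=(4, 4, 4, 8),
            rounds_range=(3, 3),
            rounds_weights=None,
            timeline_rounds_range=(3, 3),
            round_duration_s=10.0,
            seed=1,
        )
        cohort = generate_cohort(spec)
        assert [cohort.class_counts.get(c, 0) for c in range(4)] == [4, 4, 4, 8]

    def test_pair_labels_follow_cutoffs_exactly(self):
        cohort = generate_cohort(self.SPEC)
        for sub in cohort.subjects:
            for pair in pair_rounds(sub.rounds):
                assert pair.severity_label == severity_label(pair.delta_updrs)

    def test_regeneration_is_identical(self):
        a = generate_cohort(self.SPEC)
        b = generate_cohort(self.SPEC)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.seed == sb.seed
            np.testing.assert_array_equal(
                sa.rounds[0].recordings[Site.WRIST].samples,
                sb.rounds[0].recordings[Site.WRIST].samples,
            )
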