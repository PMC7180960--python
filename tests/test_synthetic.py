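import dataclasses

import numpy as np
import pytest

from habitspectrum import (
    ActivityRegistry,
    HabitTemplate,
    SimConfig,
    behavioral_spectrum,
    evaluate_recovery,
    extract_sequences,
    full_day_regime_config,
    kmeans_cluster,
    session_regime_config,
    simulate_log,
    standardize_features,
    variability_table,
    well_separated_session_config,
)
from _oracles import textbook_ari


REGISTRY = ActivityRegistry(tuple((f"act{i}", i) for i in range(1, 10)))


def one_template_config(seed=0, **noise):
    t = HabitTemplate("only", ids=(1, 2, 3), mean_durations=(5.0, 10.0, 3.0), **noise)
    return SimConfig(
        templates=(t,), weights=(1.0,), n_subjects=10, n_days=2,
        registry=REGISTRY, regime="session", seed=seed,
    )


class TestSimulateLog:
    def test_noise_free_template_repeats_exactly(self):
        events, truth = simulate_log(one_template_config())
        seqs = extract_sequences(events, session_mode=True)
        assert len(seqs) == 20
        assert all(s.ids == (1, 2, 3) and s.durations == (5.0, 10.0, 3.0) for s in seqs)
        assert set(truth.values()) == {"only"}

    def test_deterministic_given_seed(self):
        cfg = one_template_config(seed=9, duration_sd=2.0, swap_prob=0.3, drop_prob=0.2)
        assert simulate_log(cfg) == simulate_log(cfg)

    def test_different_seeds_differ(self):
        a = simulate_log(one_template_config(seed=1, duration_sd=2.0))
        b = simulate_log(one_template_config(seed=2, duration_sd=2.0))
        assert a != b

    def test_durations_floored_at_one_minute(self):
        cfg = one_template_config(duration_sd=50.0)  # huge jitter vs means 3-10 min
        events, _ = simulate_log(cfg)
        assert all(e.duration >= 1.0 for e in events)

    def test_template_frequencies_track_weights(self):
        templates = tuple(
            HabitTemplate(f"t{i}", ids=(3 * i + 1, 3 * i + 2), mean_durations=(4.0, 5.0))
            for i in range(3)
        )
        cfg = SimConfig(
            templates=templates, weights=(0.5, 0.3, 0.2), n_subjects=200, n_days=1,
            registry=REGISTRY, regime="session", seed=11,
        )
        _, truth = simulate_log(cfg)
        freqs = {t.label: 0 for t in templates}
        for label in truth.values():
            freqs[label] += 1
        for w, t in zip(cfg.weights, templates):
            assert abs(freqs[t.label] / 200 - w) <= 0.08

    def test_empty_template_list_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                templates=(), weights=(), n_subjects=1, n_days=1,
                registry=REGISTRY, regime="session",
            )

    def test_weights_must_sum_to_one(self):
        t = HabitTemplate("t", ids=(1,), mean_durations=(5.0,))
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(
                templates=(t, t), weights=(0.5, 0.6), n_subjects=1, n_days=1,
                registry=REGISTRY, regime="session",
            )

    def test_full_day_events_fall_in_their_phase(self):
        cfg = full_day_regime_config(n_subjects=2, n_days=2, seed=4)
        events, truth = simulate_log(cfg)
        seqs = extract_sequences(events, windows=cfg.phase_windows)
        assert {s.window_label for s in seqs} == {"morning", "afternoon", "night"}
        # truth covers every extracted window
        assert {s.key for s in seqs} <= set(truth)

    def test_session_templates_fit_twenty_minutes(self):
        cfg = well_separated_session_config()
        for t in cfg.templates:
            assert sum(t.mean_durations) <= 20.0


class TestEvaluateRecovery:
    def test_relabelled_identity_scores_one(self):
        truth = ["a", "a", "b", "b", "c", "c"]
        assignments = [2, 2, 0, 0, 1, 1]
        assert evaluate_recovery(assignments, truth) == pytest.approx(1.0)

    def test_single_cluster_against_balanced_truth_is_chance(self):
        truth = ["a"] * 5 + ["b"] * 5
        assert evaluate_recovery([0] * 10, truth) == pytest.approx(0.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.integers(0, 3, size=30).tolist()
        b = rng.integers(0, 3, size=30).tolist()
        assert evaluate_recovery(a, b) == pytest.approx(textbook_ari(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_recovery([0, 1], [0, 1, 2])


def _variability_matrix(seqs):
    return variability_table([behavioral_spectrum(s) for s in seqs]).to_numpy()


class TestRecoveryProperties:
    def test_well_separated_habits_recovered(self):
        """Noise-floor conditions: clustering should recover the planted habits."""
        cfg = well_separated_session_config(n_sequences=60, seed=5)
        events, truth = simulate_log(cfg)
        seqs = extract_sequences(events, session_mode=True)
        labels = [truth[s.key] for s in seqs]
        Z, _ = standardize_features(_variability_matrix(seqs))
        model = kmeans_cluster(Z, 3, restarts=10, seed=5)
        assert evaluate_recovery(model.assignments, labels) >= 0.9

    def test_recovery_degrades_with_duration_jitter(self):
        """Mean ARI over seeds is non-increasing as duration jitter grows."""
        mean_aris = []
        for sd in (0.0, 5.0, 15.0, 30.0):
            aris = []
            for seed in range(8):
                cfg = well_separated_session_config(n_sequences=40, seed=seed)
                cfg = dataclasses.replace(
                    cfg,
                    templates=tuple(
                        dataclasses.replace(t, duration_sd=sd) for t in cfg.templates
                    ),
                )
                events, truth = simulate_log(cfg)
                seqs = extract_sequences(events, session_mode=True)
                labels = [truth[s.key] for s in seqs]
                Z, _ = standardize_features(_variability_matrix(seqs))
                model = kmeans_cluster(Z, 3, restarts=8, seed=seed)
                aris.append(evaluate_recovery(model.assignments, labels))
            mean_aris.append(float(np.mean(aris)))
        assert all(b <= a + 0.02 for a, b in zip(mean_aris, mean_aris[1:]))


def test_session_regime_defaults_are_session_shaped():
    cfg = session_regime_config()
    assert cfg.regime == "session"
    assert len(cfg.registry) == 6
    events, truth = simulate_log(cfg)
    assert len(truth) == cfg.n_subjects * cfg.n_days


def test_full_day_regime_has_25_activities():
    assert len(full_day_regime_config().registry) == 25
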