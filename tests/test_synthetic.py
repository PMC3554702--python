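"""Synthetic-data generator: determinism, limits, recovery, monotonicity."""

import numpy as np
import pytest

from gnosticfield import (
    FieldConfig,
    SynthConfig,
    fit_gnostic_set,
    generate_dataset,
    mean_per_class_accuracy,
    overall_accuracy,
    predict,
    train_model,
)
from gnosticfield.gnostic_sets import AllocationPolicy
from gnosticfield.synthetic import shuffle_labels, split_dataset, _unit_rows


def _accuracy(cfg, field_cfg=None):
    tr, te = split_dataset(generate_dataset(cfg))
    model = train_model(tr, field_cfg or FieldConfig(seed=cfg.seed))
    preds, _ = predict(model, te)
    truth = [s.label for s in te.stimuli]
    return mean_per_class_accuracy(truth, preds), overall_accuracy(truth, preds)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SynthConfig(K=3, U=2, d=5, n_train=2, n_test=1,
                          locations_per_stimulus=4, seed=42)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        for s1, s2 in zip(d1.stimuli, d2.stimuli):
            assert s1.stimulus_id == s2.stimulus_id and s1.label == s2.label
            for cid in s1.channels:
                assert s1.channels[cid].vectors.tobytes() == s2.channels[cid].vectors.tobytes()
                assert s1.channels[cid].locations.tobytes() == s2.channels[cid].locations.tobytes()

    def test_different_seeds_differ(self):
        cfg1 = SynthConfig(K=2, U=1, d=4, n_train=1, n_test=1, seed=0,
                           locations_per_stimulus=4)
        cfg2 = SynthConfig(K=2, U=1, d=4, n_train=1, n_test=1, seed=1,
                           locations_per_stimulus=4)
        a = generate_dataset(cfg1).stimuli[0].channels["ch0"].vectors
        b = generate_dataset(cfg2).stimuli[0].channels["ch0"].vectors
        assert not np.array_equal(a, b)


class TestLimits:
    def test_noiseless_single_cluster_perfect_with_one_training_stimulus(self):
        cfg = SynthConfig(
            K=3, U=1, d=5, clusters_per_category=1, kappa=np.inf,
            background_fraction=0.0, locations_per_stimulus=9,
            n_train=1, n_test=3, distortion_condition=1.0, seed=3,
        )
        mpca, _ = _accuracy(cfg)
        assert mpca == 100.0

    def test_zero_concentration_is_chance_level(self):
        cfg = SynthConfig(
            K=4, U=1, d=8, kappa=0.0, locations_per_stimulus=9,
            n_train=10, n_test=25, background_fraction=0.0, seed=5,
        )
        _, overall = _accuracy(cfg)
        n = 4 * 25
        sigma = 100.0 * np.sqrt(0.25 * 0.75 / n)
        assert abs(overall - 25.0) <= 3 * sigma

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(K=1)
        with pytest.raises(ValueError):
            SynthConfig(background_fraction=1.0)
        with pytest.raises(ValueError):
            SynthConfig(channel_snr=(1.0,), U=2)


class TestShuffleLabels:
    def test_label_multiset_conserved_and_reproducible(self):
        cfg = SynthConfig(K=3, U=1, d=4, n_train=4, n_test=0,
                          locations_per_stimulus=4, seed=1)
        ds = generate_dataset(cfg)
        s1 = shuffle_labels(ds, seed=9)
        s2 = shuffle_labels(ds, seed=9)
        assert sorted(x.label for x in s1.stimuli) == sorted(x.label for x in ds.stimuli)
        assert [x.label for x in s1.stimuli] == [x.label for x in s2.stimuli]
        assert [x.label for x in s1.stimuli] != [x.label for x in ds.stimuli]

    def test_uniform_labels_unchanged_by_any_permutation(self):
        cfg = SynthConfig(K=2, U=1, d=4, n_train=3, n_test=0,
                          locations_per_stimulus=4, seed=1)
        ds = generate_dataset(cfg)
        for s in ds.stimuli:
            s.label = "cat00"
        out = shuffle_labels(ds, seed=123)
        assert [x.label for x in out.stimuli] == ["cat00"] * len(ds.stimuli)


class TestStructure:
    def test_cluster_direction_recovery(self):
        """With tight, well-separated clusters the fitted gnostic units land
        within 1e-2 radians of the true per-category directions."""
        C = 2
        cfg = SynthConfig(
            K=2, U=1, d=8, clusters_per_category=C, kappa=1e6,
            background_fraction=0.0, locations_per_stimulus=16,
            n_train=10, n_test=0, distortion_condition=1.0, seed=11,
        )
        ds = generate_dataset(cfg)
        # recompute the generator's cluster directions from its seed
        rng = np.random.default_rng(cfg.seed)
        means = _unit_rows(rng.standard_normal((1, 2, C, 8)))[0]
        for ki, cat in enumerate(ds.categories):
            X = np.vstack(
                [s.channels["ch0"].vectors for s in ds.stimuli if s.label == cat]
            )
            gs = fit_gnostic_set(_unit_rows(X), cat, "ch0",
                                 AllocationPolicy(alpha=50.0), seed=0)
            for true_dir in means[ki]:
                best_cos = float((gs.units @ true_dir).max())
                assert np.arccos(np.clip(best_cos, -1, 1)) < 1e-2

    def test_accuracy_monotone_in_background_and_concentration(self):
        base = dict(K=5, U=1, d=8, clusters_per_category=2,
                    locations_per_stimulus=16, n_train=8, n_test=6, seed=17)
        accs = [
            _accuracy(SynthConfig(**base, kappa=120.0, background_fraction=bf))[0]
            for bf in (0.0, 0.5, 0.85)
        ]
        assert accs[0] >= accs[1] >= accs[2]
        accs = [
            _accuracy(SynthConfig(**base, background_fraction=0.1, kappa=kp))[0]
            for kp in (120.0, 3.0, 0.3)
        ]
        assert accs[0] >= accs[1] >= accs[2]

    def test_spatial_channel_gets_grid_locations(self):
        cfg = SynthConfig(K=2, U=2, d=4, n_train=1, n_test=0,
                          locations_per_stimulus=9, seed=0)
        ds = generate_dataset(cfg)
        s = ds.stimuli[0]
        assert s.channels["ch0"].locations.shape == (9, 2)
        assert np.all(np.abs(s.channels["ch0"].locations) <= 1.0)
        np.testing.assert_array_equal(s.channels["ch1"].locations, np.arange(9))
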