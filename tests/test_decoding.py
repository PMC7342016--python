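import dataclasses

import numpy as np
import pytest
from sklearn.svm import SVC

from oscdecode.decoding import (
    CrossTaskTimeGeneralizer,
    DecodingConfig,
    WithinTaskDecoder,
    alpha_power_split,
    broadband_within,
    electrode_subset,
    make_pseudotrials,
    peak_alpha_band,
    train_pair_classifier,
)
from oscdecode.simulate import generate_participant
from oscdecode.timefreq import BandSpec, FrequencyGrid, TFEpochs
from .conftest import make_epochs


class TestPairClassifier:
    def test_matches_sklearn_svc(self):
        rng = np.random.default_rng(0)
        Xa = rng.normal(size=(4, 10)) + 1.0
        Xb = rng.normal(size=(4, 10)) - 1.0
        clf = train_pair_classifier(Xa, Xb)
        ref = SVC(kernel="linear", C=1.0).fit(
            np.vstack([Xa, Xb]), [0] * 4 + [1] * 4
        )
        # our convention: decision > 0 -> class a (= sklearn class 0)
        assert np.allclose(clf.weights, -ref.coef_[0], atol=1e-8)
        assert clf.bias == pytest.approx(-ref.intercept_[0], abs=1e-8)
        X = rng.normal(size=(20, 10))
        assert np.array_equal(clf.predict_a(X), ref.predict(X) == 0)

    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(1)
        Xa = rng.normal(size=(6, 5)) + 5.0
        Xb = rng.normal(size=(6, 5)) - 5.0
        clf = train_pair_classifier(Xa, Xb)
        assert clf.predict_a(Xa).all()
        assert (~clf.predict_a(Xb)).all()

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(2)
        Xa, Xb = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        c1 = train_pair_classifier(Xa, Xb)
        c2 = train_pair_classifier(Xb, Xa)
        # agreement up to the solver's stopping tolerance
        assert np.allclose(c1.weights, -c2.weights, atol=1e-3)
        assert c1.bias == pytest.approx(-c2.bias, abs=1e-3)

    def test_random_labels_score_at_chance(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=(200, 8))
        clf = train_pair_classifier(train[:100], train[100:])
        test = rng.normal(size=(4000, 8))
        # random direction on fresh noise: half predicted as class a
        frac = clf.predict_a(test).mean()
        assert frac == pytest.approx(0.5, abs=0.06)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            train_pair_classifier(np.empty((0, 3)), np.ones((2, 3)))


class TestPseudoTrials:
    def test_quarter_shares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        y = np.repeat([1, 2], 40)
        ps = make_pseudotrials(X, y, 4, rng)
        assert ps.vectors.shape == (2, 4, 5)
        # partition: the 4 pseudo-trials average all 40 trials exactly once
        for ci, label in enumerate(ps.conditions):
            assert np.allclose(
                ps.vectors[ci].mean(axis=0), X[y == label].mean(axis=0), atol=1e-12
            )

    def test_remainder_dropped(self):
        rng = np.random.default_rng(0)
        X = np.arange(41, dtype=float)[:, None]
        y = np.ones(41)
        ps = make_pseudotrials(X, y, 4, rng)
        assert ps.vectors.shape == (1, 4, 1)
        # 4 shares of 10: total mass misses exactly one trial
        used_sum = ps.vectors.sum() * 10
        assert used_sum != X.sum()  # one value dropped
        assert abs(used_sum - X.sum()) <= X.max()

    def test_identical_trials_identical_pseudotrials(self):
        X = np.ones((12, 3))
        ps = make_pseudotrials(X, np.ones(12), 4, np.random.default_rng(0))
        assert np.allclose(ps.vectors, 1.0)

    def test_too_few_trials_errors(self):
        with pytest.raises(ValueError):
            make_pseudotrials(np.ones((3, 2)), np.ones(3), 4)

    def test_partitions_redrawn(self):
        rng = np.random.default_rng(0)
        X = np.random.default_rng(1).normal(size=(16, 2))
        y = np.ones(16)
        a = make_pseudotrials(X, y, 4, rng).vectors
        b = make_pseudotrials(X, y, 4, rng).vectors
        assert not np.allclose(a, b)


def _separable_bands(n_obj=4, n_pseudo_trials=16, n_feat=6, n_times=5, sep=5.0, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    centers = sep * rng.normal(size=(n_obj, n_feat))
    y = np.repeat(np.arange(1, n_obj + 1), n_pseudo_trials)
    X = centers[y - 1][:, :, None] + noise * rng.normal(
        size=(len(y), n_feat, n_times)
    )
    return X, y


class TestCrossTaskTimeGen:
    def test_separable_signal_decodes_perfectly(self):
        # same class centers in both tasks, tiny noise: a shared code
        rng = np.random.default_rng(3)
        centers = 5.0 * rng.normal(size=(4, 6))
        yp = np.repeat(np.arange(1, 5), 16)
        Xp = centers[yp - 1][:, :, None] + 0.05 * rng.normal(size=(64, 6, 3))
        Xi = centers[yp - 1][:, :, None] + 0.05 * rng.normal(size=(64, 6, 4))
        est = CrossTaskTimeGeneralizer(n_repeats=2, random_state=0).fit(
            Xp, yp, Xi, yp
        )
        assert est.accuracy_.shape == (3, 4)
        assert np.all(est.accuracy_ > 95.0)

    def test_label_shuffle_is_at_chance(self):
        rng = np.random.default_rng(4)
        Xp = rng.normal(size=(48, 6, 4))
        Xi = rng.normal(size=(48, 6, 5))
        y = np.repeat(np.arange(1, 7), 8)
        est = CrossTaskTimeGeneralizer(n_repeats=5, random_state=0).fit(Xp, y, Xi, y)
        assert est.accuracy_.mean() == pytest.approx(50.0, abs=2.5)

    def test_accuracy_is_mean_of_pairs(self):
        Xp, yp = _separable_bands(noise=1.0, seed=5)
        Xi, yi = _separable_bands(noise=1.0, seed=6)
        est = CrossTaskTimeGeneralizer(n_repeats=2, random_state=1).fit(
            Xp, yp, Xi, yi
        )
        iu = np.triu_indices(4, k=1)
        assert np.allclose(
            est.per_pair_[:, :, iu[0], iu[1]].mean(axis=-1), est.accuracy_
        )
        # symmetry and NaN diagonal
        assert np.allclose(
            est.per_pair_[..., iu[0], iu[1]], est.per_pair_[..., iu[1], iu[0]]
        )
        assert np.all(np.isnan(est.per_pair_[..., 0, 0]))

    def test_relabeling_permutes_per_pair(self, monkeypatch):
        """Renaming objects permutes the pairwise map and nothing else.

        Pseudo-trial partitions are frozen to a deterministic rule so the
        comparison isolates the estimator's label bookkeeping from the
        random partition draws.
        """
        import oscdecode.decoding as dec

        def fixed_partition(X, conditions, n_pseudo=4, rng=None):
            X = np.asarray(X)
            labels = np.unique(conditions)
            out = []
            for label in labels:
                idx = np.flatnonzero(conditions == label)
                share = len(idx) // n_pseudo
                out.append(
                    X[idx[: share * n_pseudo]].reshape(
                        (n_pseudo, share) + X.shape[1:]
                    ).mean(axis=1)
                )
            return dec.PseudoTrialSet(np.stack(out), labels, n_pseudo)

        monkeypatch.setattr(dec, "make_pseudotrials", fixed_partition)
        rng = np.random.default_rng(7)
        X = rng.normal(size=(32, 5, 3))
        y = np.repeat(np.arange(1, 5), 8)
        perm = np.array([3, 1, 4, 2])  # new label of old object k = perm[k-1]
        est1 = dec.CrossTaskTimeGeneralizer(n_repeats=1, random_state=2).fit(
            X, y, X.copy(), y
        )
        est2 = dec.CrossTaskTimeGeneralizer(n_repeats=1, random_state=2).fit(
            X, perm[y - 1], X.copy(), perm[y - 1]
        )
        p = perm - 1
        assert np.allclose(
            est1.per_pair_, est2.per_pair_[:, :, p][:, :, :, p], equal_nan=True
        )
        assert np.allclose(est1.accuracy_, est2.accuracy_)

    def test_single_directions_average_to_both(self):
        rng = np.random.default_rng(8)
        Xp = rng.normal(size=(32, 5, 3))
        Xi = rng.normal(size=(32, 5, 4))
        y = np.repeat(np.arange(1, 5), 8)
        kw = dict(n_repeats=2, random_state=3)
        both = CrossTaskTimeGeneralizer(directions="both", **kw).fit(Xp, y, Xi, y)
        d1 = CrossTaskTimeGeneralizer(directions="train_perception", **kw).fit(Xp, y, Xi, y)
        d2 = CrossTaskTimeGeneralizer(directions="train_imagery", **kw).fit(Xp, y, Xi, y)
        assert both.accuracy_.shape == d1.accuracy_.shape == d2.accuracy_.shape
        assert np.allclose(both.accuracy_, (d1.accuracy_ + d2.accuracy_) / 2)


class TestWithinTask:
    def test_separable_signal_perfect(self):
        rng = np.random.default_rng(9)
        centers = 5.0 * rng.normal(size=(4, 6))
        y = np.repeat(np.arange(1, 5), 16)
        X = centers[y - 1][:, :, None] + 0.05 * rng.normal(size=(64, 6, 3))
        est = WithinTaskDecoder(n_repeats=2, random_state=0).fit(X, y)
        assert est.accuracy_.shape == (3,)
        assert np.all(est.accuracy_ > 95.0)

    def test_noise_at_chance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(64, 6, 4))
        y = np.repeat(np.arange(1, 5), 16)
        est = WithinTaskDecoder(n_repeats=5, random_state=0).fit(X, y)
        assert est.accuracy_.mean() == pytest.approx(50.0, abs=4.0)


class TestElectrodeSubset:
    def test_posterior_subset_of_epochs(self, tiny_participant):
        participant, truth = tiny_participant
        # generic channel names: montage-based splitting must fail loudly
        with pytest.raises(ValueError):
            electrode_subset(participant.perception, "posterior")

    def test_subset_names(self):
        eps = make_epochs(n_channels=4)
        eps.channels = ["Oz", "Cz", "Fp1", "POz"]
        post = electrode_subset(eps, "posterior")
        ant = electrode_subset(eps, "anterior")
        assert post.channels == ["Oz", "Cz", "POz"]
        assert ant.channels == ["Cz", "Fp1"]
        with pytest.raises(ValueError):
            electrode_subset(eps, "central")


class TestPeakAlpha:
    @pytest.mark.parametrize("planted,expected", [(10.0, 10), (13.0, 13)])
    def test_recovers_planted_frequency(self, tiny_config, planted, expected):
        cfg = dataclasses.replace(
            tiny_config,
            shared_band=(planted, planted),  # carrier exactly at `planted`
            snr=1.8,
            trials_per_object_per_task=16,
            background_alpha_amp=0.0,  # keep the 10 Hz background from masking
        )
        participant, _ = generate_participant(cfg, 0)
        res = peak_alpha_band(
            participant.perception,
            DecodingConfig(n_repeats=4, perception_stride=4, seed=0),
        )
        assert res["peak_freq"] == expected
        assert res["band_range"] == (expected - 1, expected + 1)

    def test_flat_data_ties_to_lowest(self):
        data = np.ones((8, 2, 300))
        eps = make_epochs(n_trials=8, n_channels=2, data=data, n_objects=2)
        res = peak_alpha_band(eps, DecodingConfig(n_repeats=1, perception_stride=6))
        assert res["peak_freq"] == 8
        assert all(a == pytest.approx(50.0) for a in res["accuracies"].values())


def _normalized_tf(stat_per_trial, n_channels=2, n_bins=2, n_times=20):
    n_trials = len(stat_per_trial)
    power = np.tile(
        np.asarray(stat_per_trial, dtype=float)[:, None, None, None],
        (1, n_channels, n_bins, n_times),
    )
    times = np.arange(n_times) * 20.0
    return TFEpochs(
        power=power,
        times=times,
        grid=FrequencyGrid((9.0, 11.0)),
        channels=[f"CH{i:02d}" for i in range(n_channels)],
        task=np.array(["perception"] * n_trials),
        object_id=np.arange(1, n_trials + 1),
        sampling_rate=50.0,
        normalized=True,
        baseline_window=(-500.0, -300.0),
    )


class TestAlphaPowerSplit:
    def test_split_and_equalize(self):
        tf = _normalized_tf([1.0, 2.0, 3.0, -1.0, -2.0, 0.0])
        band = BandSpec("alpha", (8, 13), (0, 1))
        enh, sup = alpha_power_split(tf, band, window=(0.0, 400.0),
                                     rng=np.random.default_rng(0))
        assert len(enh) == len(sup) == 3
        assert set(sup) == {3, 4, 5}  # 0 dB counts as suppressed
        assert set(enh).issubset({0, 1, 2})

    def test_all_enhanced_errors(self):
        tf = _normalized_tf([1.0, 2.0, 3.0, 4.0])
        band = BandSpec("alpha", (8, 13), (0, 1))
        with pytest.raises(ValueError):
            alpha_power_split(tf, band)

    def test_symmetric_null_splits_evenly(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=400)
        tf = _normalized_tf(stats)
        band = BandSpec("alpha", (8, 13), (0, 1))
        enh, sup = alpha_power_split(tf, band, window=(0.0, 400.0), rng=rng)
        n = min((stats > 0).sum(), (stats <= 0).sum())
        assert len(enh) == len(sup) == n
        assert n > 150  # near 50/50

    def test_requires_normalized(self):
        tf = _normalized_tf([1.0, -1.0])
        tf.normalized = False
        with pytest.raises(ValueError):
            alpha_power_split(tf, BandSpec("alpha", (8, 13), (0, 1)))


class TestBroadband:
    def test_phase_locked_signal_decodable_within_task(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, phase_locked=True, snr=3.0)
        participant, _ = generate_participant(cfg, 0)
        dc = DecodingConfig(
            n_repeats=2,
            perception_window=(0.0, 800.0),
            perception_stride=20,  # 100 ms steps at 200 Hz
            seed=0,
        )
        tc = broadband_within(participant.perception, dc)
        times = tc.times
        lo, hi = cfg.perception_latency
        inwin = tc.accuracy[(times >= lo) & (times < hi)]
        base = tc.accuracy[times < lo]
        assert inwin.mean() > base.mean() + 10.0
        assert inwin.mean() > 60.0

    def test_snr_zero_at_chance(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, snr=0.0)
        participant, _ = generate_participant(cfg, 0)
        dc = DecodingConfig(
            n_repeats=2, perception_window=(0.0, 800.0), perception_stride=20, seed=0
        )
        tc = broadband_within(participant.perception, dc)
        assert tc.accuracy.mean() == pytest.approx(50.0, abs=6.0)
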