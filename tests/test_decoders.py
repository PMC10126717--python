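"""HMM-NB and static decoders: training, filtering, per-trial prediction."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import rpnidecode as rd
from rpnidecode import decoders as dc, signal_processing as sp, synth_emg as se


def brute_force_class_posteriors(model: dc.HmmNbModel, X: np.ndarray) -> np.ndarray:
    """Filtered class posteriors by exhaustive path enumeration.

    Independent of the forward recursion: sums the joint probability of
    every state path prefix, using scipy's Gaussian pdf for emissions.
    """
    if model.emission_domain == "log":
        Y = np.log(np.maximum(X, dc.LOG_EPS))
        var = model.variances + model.drift_tolerance**2
    else:
        Y = X
        var = model.variances + (model.drift_tolerance * model.means) ** 2
    B, S = Y.shape[1], model.n_states
    emis = np.array([
        [np.prod(norm.pdf(Y[:, t], model.means[s], np.sqrt(var[s]))) for s in range(S)]
        for t in range(B)
    ])
    out = np.zeros((B, len(model.classes)))
    for t in range(B):
        probs = np.zeros(S)
        for path in itertools.product(range(S), repeat=t + 1):
            p = model.initial[path[0]] * emis[0, path[0]]
            for i in range(1, t + 1):
                p *= model.transition[path[i - 1], path[i]] * emis[i, path[i]]
            probs[path[-1]] += p
        probs /= probs.sum()
        for s in range(S):
            out[t, model.state_to_class[s]] += probs[s]
    return out


def _random_model(rng, n_states, n_channels, domain):
    trans = rng.uniform(0.1, 1.0, size=(n_states, n_states))
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.uniform(0.1, 1.0, size=n_states)
    init /= init.sum()
    classes = [f"c{k}" for k in range(n_states)]
    return dc.HmmNbModel(
        classes=classes,
        states_per_class=1,
        initial=init,
        transition=trans,
        means=rng.uniform(0.5, 3.0, size=(n_states, n_channels)),
        variances=rng.uniform(0.05, 0.5, size=(n_states, n_channels)),
        state_to_class=np.arange(n_states),
        emission_domain=domain,
        drift_tolerance=0.0,
    )


class TestForwardFilter:
    @pytest.mark.parametrize("domain", ["linear", "log"])
    @pytest.mark.parametrize("n_states,n_bins", [(1, 1), (2, 3), (3, 4), (2, 4)])
    def test_matches_path_enumeration(self, domain, n_states, n_bins):
        rng = np.random.default_rng(10 * n_states + n_bins)
        for _ in range(5):
            model = _random_model(rng, n_states, 2, domain)
            X = rng.uniform(0.5, 3.0, size=(2, n_bins))
            got = dc.forward_filter(model, X).posterior
            want = brute_force_class_posteriors(model, X)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_posterior_rows_normalised(self, grip_model, calibration):
        _, feats, _ = calibration
        stream = dc.forward_filter(grip_model, feats)
        np.testing.assert_allclose(stream.posterior.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(stream.argmax, stream.posterior.argmax(axis=1))

    def test_uniform_emissions_and_transitions_give_uniform_posterior(self):
        model = dc.HmmNbModel(
            classes=["a", "b"], states_per_class=1,
            initial=np.array([0.5, 0.5]),
            transition=np.full((2, 2), 0.5),
            means=np.ones((2, 1)), variances=np.ones((2, 1)),
            state_to_class=np.arange(2), emission_domain="linear", drift_tolerance=0.0,
        )
        stream = dc.forward_filter(model, np.full((1, 5), 2.0))
        np.testing.assert_allclose(stream.posterior, 0.5, atol=1e-12)

    def test_channel_mismatch_rejected(self, grip_model):
        with pytest.raises(ValueError, match="channel"):
            dc.forward_filter(grip_model, np.ones((2, 5)))

    def test_channel_permutation_invariance(self, grip_model, calibration):
        _, feats, _ = calibration
        perm = np.array([3, 0, 5, 1, 4, 2])
        permuted = dc.HmmNbModel(
            classes=grip_model.classes, states_per_class=1,
            initial=grip_model.initial, transition=grip_model.transition,
            means=grip_model.means[:, perm], variances=grip_model.variances[:, perm],
            state_to_class=grip_model.state_to_class,
            emission_domain=grip_model.emission_domain,
            drift_tolerance=grip_model.drift_tolerance,
        )
        a = dc.forward_filter(grip_model, feats.mav).argmax
        b = dc.forward_filter(permuted, feats.mav[perm]).argmax
        np.testing.assert_array_equal(a, b)


class TestTrainHmmNb:
    def test_single_class_constant_features(self):
        X = np.full((2, 40), 3.0)
        y = np.array(["fist"] * 40)
        model = dc.train_hmm_nb(X, y)
        np.testing.assert_allclose(model.mav_means, 3.0, rtol=1e-3)
        assert model.transition[0, 0] > 0.9

    def test_alternating_blocks_have_cross_transitions(self):
        X = np.ones((1, 40))
        y = np.array((["a"] * 10 + ["b"] * 10) * 2)
        model = dc.train_hmm_nb(X, y)
        assert np.all(model.transition > 0)  # add-one smoothing
        i, j = model.classes.index("a"), model.classes.index("b")
        assert model.transition[i, j] > model.transition[j, i] * 0.1

    def test_missing_class_named_in_error(self):
        X = np.ones((1, 20))
        y = np.array(["a"] * 20)
        with pytest.raises(ValueError, match="b"):
            dc.train_hmm_nb(X, y, classes=["a", "b"])

    def test_emission_means_recover_generator_truth(self, grip_config, grip_model):
        """Calibration-recovered emission means (µV) land within 10% of
        the generator's plateau MAV for the active channels."""
        for k, cls in enumerate(grip_model.classes):
            if cls == "rest":
                continue
            truth = np.array([se.plateau_mav(ch, cls) for ch in grip_config.channels])
            got = grip_model.mav_means[k]
            assert np.all(np.abs(got - truth) / truth < 0.10), cls

    def test_states_per_class_splits_runs_temporally(self):
        X = np.concatenate([np.full((1, 20), 1.0), np.full((1, 20), 9.0)], axis=1)
        y = np.array(["m"] * 40)
        model = dc.train_hmm_nb(X, y, states_per_class=2, emission_domain="linear")
        assert model.n_states == 2
        assert model.means[0, 0] == pytest.approx(1.0)
        assert model.means[1, 0] == pytest.approx(9.0)


class TestStaticModels:
    def _separable_trials(self, n_per_class=3, n_bins=4):
        trials = []
        for i, cls in enumerate(["a", "b"]):
            for t in range(n_per_class):
                trials.append((np.full((2, n_bins), 10.0 * i + 1.0), cls))
        return trials

    @pytest.mark.parametrize("kind", ["nb", "lda"])
    def test_disjoint_classes_fit_perfectly(self, kind):
        trials = self._separable_trials()
        model = dc.train_static(trials, kind)
        preds = [dc.predict_trial(model, X) for X, _ in trials]
        assert preds == [c for _, c in trials]

    def test_identical_features_fall_back_to_prior(self):
        trials = [(np.ones((1, 3)), "a")] * 2 + [(np.ones((1, 3)), "b")] * 4
        model = dc.train_static(trials, "nb")
        assert dc.predict_trial(model, np.ones((1, 3))) == "b"

    def test_too_few_classes_or_trials_rejected(self):
        with pytest.raises(ValueError):
            dc.train_static([(np.ones((1, 2)), "a")] * 4, "nb")
        with pytest.raises(ValueError):
            dc.train_static([(np.ones((1, 2)), "a"), (np.ones((1, 2)), "b")], "lda")

    def test_lda_matches_sklearn_on_well_conditioned_data(self):
        """Independent cross-check of the LDA discriminant against
        scikit-learn's implementation."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(0)
        trials = []
        for i, cls in enumerate(["a", "b", "c"]):
            mu = np.array([3.0 * i, 1.0 + i])
            for _ in range(8):
                trials.append((mu[:, None] + 0.4 * rng.standard_normal((2, 6)), cls))
        model = dc.train_static(trials, "lda")
        X = np.concatenate([t.T for t, _ in trials])
        y = np.repeat(["a", "b", "c"], 8 * 6)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        probe = rng.uniform(0, 6, size=(40, 2))
        ours = [dc.predict_static(model, p) for p in probe]
        theirs = list(sk.predict(probe))
        agree = np.mean([a == b for a, b in zip(ours, theirs)])
        assert agree >= 0.95

    def test_nb_matches_sklearn(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(1)
        trials = []
        for i, cls in enumerate(["a", "b"]):
            for _ in range(6):
                trials.append((5.0 * i + rng.standard_normal((2, 5)), cls))
        model = dc.train_static(trials, "nb")
        X = np.concatenate([t.T for t, _ in trials])
        y = np.repeat(["a", "b"], 6 * 5)
        sk = GaussianNB().fit(X, y)
        probe = rng.uniform(-2, 7, size=(40, 2))
        ours = [dc.predict_static(model, p) for p in probe]
        assert np.mean([a == b for a, b in zip(ours, sk.predict(probe))]) >= 0.95


class TestPredictTrial:
    def test_single_bin_equals_per_bin(self, grip_model, calibration):
        _, feats, _ = calibration
        one = feats.mav[:, 100:101]
        stream = dc.forward_filter(grip_model, one)
        assert dc.predict_trial(grip_model, one) == stream.labels[0]

    def test_hmm_mode_rule(self):
        model = dc.HmmNbModel(
            classes=["a", "b"], states_per_class=1,
            initial=np.array([0.5, 0.5]), transition=np.full((2, 2), 0.5),
            means=np.array([[1.0], [5.0]]), variances=np.array([[0.1], [0.1]]),
            state_to_class=np.arange(2), emission_domain="linear", drift_tolerance=0.0,
        )
        X = np.array([[1.0, 1.0, 5.0]])
        assert dc.predict_trial(model, X) == "a"
        # tie: two bins each; earliest-achieved class wins
        X = np.array([[5.0, 1.0, 1.0, 5.0]])
        assert dc.predict_trial(model, X) == "b"

    def test_trial_average_rule_differs_from_bin_majority(self):
        """The trial-average rule can overrule the bin-wise majority: two
        of three bins classify as the low class, but the averaged feature
        lands in the high class's half-space."""
        trials = [(np.full((1, 3), 0.0), "lo")] * 2 + [(np.full((1, 3), 10.0), "hi")] * 2
        model = dc.train_static(trials, "lda")
        X = np.array([[4.0, 4.0, 10.0]])  # bins: lo, lo, hi -> majority lo
        bin_preds = [dc.predict_static(model, X[:, i]) for i in range(3)]
        assert bin_preds.count("lo") == 2
        assert dc.predict_trial(model, X) == "hi"  # mean = 6 > 5


class TestLooCrossValidation:
    def test_separable_data_scores_one(self):
        trials = []
        for i, cls in enumerate(["a", "b", "c"]):
            for _ in range(3):
                trials.append((np.full((2, 3), 5.0 * i + 1.0), cls))
        assert dc.loo_cross_validate(trials, "nb") == 1.0

    def test_fold_count(self, monkeypatch):
        trials = [(np.full((1, 2), 1.0 + i % 2), "ab"[i % 2]) for i in range(8)]
        calls = []
        orig = dc._train_any
        monkeypatch.setattr(dc, "_train_any", lambda *a, **k: calls.append(1) or orig(*a, **k))
        dc.loo_cross_validate(trials, "nb")
        assert len(calls) == len(trials)

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c", "d"]
        trials = []
        for i, cls in enumerate(classes):
            for _ in range(25):
                trials.append((10.0 * i + rng.standard_normal((2, 4)), cls))
        labels = [c for _, c in trials]
        shuffled = list(rng.permutation(labels))
        trials = [(X, c) for (X, _), c in zip(trials, shuffled)]
        acc = dc.loo_cross_validate(trials, "nb")
        # chance = 1/4; 3-sigma binomial band at n = 100
        assert abs(acc - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / 100)


class TestMonotoneDegradation:
    def test_accuracy_degrades_with_class_separation(self):
        """Per-bin decoding accuracy is non-increasing (within estimation
        noise) as the grip gain patterns are interpolated toward their
        common mean."""
        base = rd.default_config(sample_rate=1000)
        grips = [m for m in base.movements if m != "rest"]
        gbar = {ch.name: np.mean([ch.gain(g) for g in grips]) for ch in base.channels}

        def channels_at(alpha):
            return tuple(
                se.ChannelSpec(
                    ch.name, ch.source_kind, ch.noise_floor_rms,
                    {m: (gbar[ch.name] + alpha * (ch.gain(m) - gbar[ch.name])
                         if m != "rest" else 0.0)
                     for m in base.movements},
                )
                for ch in base.channels
            )

        accs = []
        for alpha in (1.0, 0.75, 0.5, 0.25, 0.0):
            chans = channels_at(alpha)
            sess = se.identity_session(chans, seed=60)
            cal = se.generate_calibration_session(
                base.movements, 3, chans, sess, sample_rate=1000,
                trial_duration_s=1.5, rest_gap_s=0.5,
            )
            feats = sp.compute_mav(cal.samples, sample_rate=1000)
            labs = sp.bin_labels(cal.labels, 1000)[: feats.n_bins]
            model = dc.train_hmm_nb(feats, labs, classes=list(base.movements))
            test_sess = se.identity_session(chans, seed=61)
            test = se.generate_calibration_session(
                base.movements, 3, chans, test_sess, sample_rate=1000,
                trial_duration_s=1.5, rest_gap_s=0.5,
            )
            tf = sp.compute_mav(test.samples, sample_rate=1000)
            tl = sp.bin_labels(test.labels, 1000)[: tf.n_bins]
            pred = dc.forward_filter(model, tf).labels
            active = tl != "rest"
            accs.append(float(np.mean(pred[active] == tl[active])))
        assert all(b <= a + 0.02 for a, b in zip(accs, accs[1:])), accs
        assert accs[-1] < accs[0]
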