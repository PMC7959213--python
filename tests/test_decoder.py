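import numpy as np
import pytest
from scipy import stats

from cbloop.decoder import (
    BackwardModel,
    ScorePair,
    ScoreStream,
    build_lagged_design,
    crossval_accuracy,
    decide,
    default_lags,
    reconstruct,
    score_window,
    solve_ridge,
    stream_scores,
    train_backward_model,
)
from cbloop.preprocess import EEGSegment, preprocess_training
from cbloop.stimulus import make_templates
from cbloop.synth import AttentionTrace, EEGGenParams, simulate_trial_eeg

FS = 256.0


def small_model(rng, n_channels=3, lags_s=(0.0, 1 / FS, 3 / FS)):
    lags = np.asarray(lags_s)
    return BackwardModel(
        weights=rng.standard_normal((n_channels, lags.size)),
        lags=lags,
        ridge_lambda=0.0,
        fs=FS,
    )


def brute_force_reconstruct(weights, lag_samples, data):
    """Nested-loop transcription of yhat_t = sum_ck w_ck R[t+lag_k, c]."""
    n, n_ch = data.shape
    t0 = max(0, -min(lag_samples))
    t1 = n - max(0, max(lag_samples))
    out = []
    for t in range(t0, t1):
        acc = 0.0
        for c in range(n_ch):
            for k, lag in enumerate(lag_samples):
                acc += weights[c, k] * data[t + lag, c]
        out.append(acc)
    return np.array(out), t0


def noiseless_trials(n_trials=6, duration=5.0, n_channels=4, unatt=0.0):
    tpl = make_templates(fs=FS, duration=duration)
    gen = EEGGenParams(
        n_channels=n_channels, fs_raw=2048.0, attended_gain=1.0,
        unattended_gain=unatt, noise_sd=1e-8, noise_spectrum="white",
        mixing_seed=5,
    )
    trials = []
    for i in range(n_trials):
        label = "face" if i % 2 == 0 else "spiral"
        trace = AttentionTrace(duration=duration, initial_state=label)
        raw = simulate_trial_eeg(tpl, trace, gen, seed=i)
        trials.append((preprocess_training(raw, fs_out=FS), label))
    return trials, tpl


class TestTraining:
    def test_small_instance_matches_normal_equations(self, rng):
        # brute-force oracle: w = (X'X + lam_eff I)^-1 X'y on a tiny case
        lags = np.array([0.0, 1 / FS, 2 / FS])
        lag_samples = np.array([0, 1, 2])
        tpl = make_templates(fs=FS, duration=200 / FS)
        lam = 0.37
        labels = ["face", "spiral", "face", "spiral"]
        datasets = [rng.standard_normal((200, 2)) for _ in labels]
        trials = [(EEGSegment(data=d, fs=FS), lab)
                  for d, lab in zip(datasets, labels)]
        model = train_backward_model(trials, tpl, lags=lags, ridge_lambda=lam)
        rows = 200 - 2
        blocks, ys = [], []
        for d, lab in zip(datasets, labels):
            X = np.zeros((rows, 6))
            for t in range(rows):
                for c in range(2):
                    for k in range(3):
                        X[t, c * 3 + k] = d[t + lag_samples[k], c]
            blocks.append(X)
            ys.append(tpl.template(lab)[:rows])
        Xfull, y = np.vstack(blocks), np.concatenate(ys)
        gram = Xfull.T @ Xfull
        lam_eff = lam * np.trace(gram) / 6
        w_oracle = np.linalg.solve(gram + lam_eff * np.eye(6), Xfull.T @ y)
        np.testing.assert_allclose(model.weights.ravel(), w_oracle, rtol=1e-8)

    def test_noiseless_training_reconstruction(self):
        trials, tpl = noiseless_trials(unatt=0.0)
        model = train_backward_model(trials, tpl, lags=default_lags(FS, 0.1),
                                     ridge_lambda=1e-6)
        for seg, label in trials:
            yhat, t0 = reconstruct(model, seg)
            # skip the causal-filter transient at the segment head
            y = tpl.template(label)[t0 + 256 : t0 + yhat.size]
            r = np.corrcoef(yhat[256:], y)[0, 1]
            assert r > 0.99

    def test_duplicating_trials_leaves_weights_unchanged(self):
        trials, tpl = noiseless_trials(n_trials=4)
        lags = default_lags(FS, 0.05)
        m1 = train_backward_model(trials, tpl, lags=lags, ridge_lambda=0.1)
        m2 = train_backward_model(trials * 2, tpl, lags=lags, ridge_lambda=0.1)
        np.testing.assert_allclose(m1.weights, m2.weights, rtol=1e-9)

    def test_singular_design_without_ridge_raises(self):
        # duplicated channel makes X'X exactly singular
        data = np.random.default_rng(0).standard_normal((100, 1))
        seg = EEGSegment(data=np.hstack([data, data]), fs=FS)
        tpl = make_templates(fs=FS, duration=100 / FS)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            train_backward_model(
                [(seg, "face"), (seg, "spiral")] * 2, tpl,
                lags=np.array([0.0]), ridge_lambda=0.0,
            )

    def test_too_few_trials_per_label(self):
        trials, tpl = noiseless_trials(n_trials=4)
        unbalanced = [t for t in trials if t[1] == "face"] + trials[1:2]
        with pytest.raises(ValueError, match="at least 2"):
            train_backward_model(unbalanced, tpl)


class TestReconstruct:
    def test_all_zero_weights(self, rng, segment_factory):
        model = small_model(rng)
        model.weights[:] = 0.0
        yhat, _ = reconstruct(model, segment_factory(n_channels=3))
        np.testing.assert_array_equal(yhat, 0.0)

    def test_identity_single_lag_returns_channel(self, rng, segment_factory):
        seg = segment_factory(n_channels=3)
        weights = np.zeros((3, 1))
        weights[1, 0] = 1.0
        model = BackwardModel(weights=weights, lags=np.array([0.0]),
                              ridge_lambda=0.0, fs=FS)
        yhat, t0 = reconstruct(model, seg)
        assert t0 == 0
        np.testing.assert_allclose(yhat, seg.data[:, 1])

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force(self, trial, segment_factory):
        rng = np.random.default_rng(100 + trial)
        model = small_model(rng)
        seg = segment_factory(n_samples=64, n_channels=3)
        yhat, t0 = reconstruct(model, seg)
        expected, t0_exp = brute_force_reconstruct(
            model.weights, model.lag_samples(), seg.data
        )
        assert t0 == t0_exp
        np.testing.assert_allclose(yhat, expected, rtol=1e-10)

    def test_segment_shorter_than_lag_span_rejected(self, rng):
        model = small_model(rng, lags_s=(0.0, 0.5))
        seg = EEGSegment(data=np.zeros((64, 3)), fs=FS)
        with pytest.raises(ValueError, match="lag span"):
            reconstruct(model, seg)


class TestScoring:
    def test_face_segment_scores_plus_minus_one(self, templates_5s, rng):
        weights = np.zeros((2, 1))
        weights[0, 0] = 1.0
        model = BackwardModel(weights=weights, lags=np.array([0.0]),
                              ridge_lambda=0.0, fs=FS)
        n = int(3.0 * FS)
        data = np.column_stack([
            templates_5s.y_face[:n], rng.standard_normal(n)
        ])
        pair = score_window(model, EEGSegment(data=data, fs=FS), templates_5s)
        assert pair.c_face == pytest.approx(1.0, abs=1e-12)
        assert pair.c_spiral == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_pearson(self, templates_5s, rng):
        model = small_model(rng, n_channels=2, lags_s=(0.0,))
        n = int(3.0 * FS)
        seg = EEGSegment(data=rng.standard_normal((n, 2)), fs=FS)
        pair = score_window(model, seg, templates_5s, window_start_sample=128)
        yhat, t0 = reconstruct(model, seg)
        lo = 128 + t0
        r_face = stats.pearsonr(yhat, templates_5s.y_face[lo : lo + n]).statistic
        r_spiral = stats.pearsonr(yhat, templates_5s.y_spiral[lo : lo + n]).statistic
        assert pair.c_face == pytest.approx(r_face, abs=1e-12)
        assert pair.c_spiral == pytest.approx(r_spiral, abs=1e-12)

    def test_zero_variance_reconstruction_scores_zero(self, templates_5s, caplog):
        model = BackwardModel(weights=np.zeros((2, 1)), lags=np.array([0.0]),
                              ridge_lambda=0.0, fs=FS)
        seg = EEGSegment(data=np.ones((int(3 * FS), 2)), fs=FS)
        with caplog.at_level("WARNING", logger="cbloop.decoder"):
            pair = score_window(model, seg, templates_5s)
        assert pair.c_face == 0.0 and pair.c_spiral == 0.0
        assert any("zero-variance" in m for m in caplog.messages)

    def test_wrong_window_length_rejected(self, templates_5s, rng):
        model = small_model(rng, n_channels=2, lags_s=(0.0,))
        seg = EEGSegment(data=rng.standard_normal((100, 2)), fs=FS)
        with pytest.raises(ValueError, match="window"):
            score_window(model, seg, templates_5s)

    def test_scale_invariance(self, templates_6s, rng):
        model = small_model(rng, n_channels=4, lags_s=(0.0, 2 / FS))
        data = rng.standard_normal((int(6 * FS), 4))
        s1 = stream_scores(model, EEGSegment(data=data, fs=FS), templates_6s)
        s2 = stream_scores(
            model, EEGSegment(data=17.3 * data, fs=FS), templates_6s
        )
        np.testing.assert_allclose(
            s1.differences(), s2.differences(), atol=1e-12
        )


class TestStreamScores:
    def test_pair_count_five_second_trial(self, templates_5s, rng):
        model = small_model(rng, n_channels=2, lags_s=(0.0,))
        seg = EEGSegment(data=rng.standard_normal((1280, 2)), fs=FS)
        stream = stream_scores(model, seg, templates_5s)
        assert len(stream) == 9
        ends = [p.window_end for p in stream.pairs]
        np.testing.assert_allclose(ends, 3.0 + 0.25 * np.arange(9))

    def test_equivalent_to_independent_windows(self, templates_6s, rng):
        model = small_model(rng, n_channels=3)
        seg = EEGSegment(data=rng.standard_normal((1536, 3)), fs=FS)
        stream = stream_scores(model, seg, templates_6s)
        win = int(3.0 * FS)
        for i, pair in enumerate(stream.pairs):
            start = i * 64
            sub = EEGSegment(data=seg.data[start : start + win], fs=FS)
            ref = score_window(model, sub, templates_6s,
                               window_start_sample=start)
            assert pair.c_face == pytest.approx(ref.c_face, abs=1e-12)
            assert pair.c_spiral == pytest.approx(ref.c_spiral, abs=1e-12)

    def test_stationary_signal_stable_scores(self, templates_6s):
        model = BackwardModel(weights=np.array([[1.0], [0.0]]),
                              lags=np.array([0.0]), ridge_lambda=0.0, fs=FS)
        n = 1536
        data = np.column_stack([templates_6s.y_face, np.zeros(n)])
        stream = stream_scores(model, EEGSegment(data=data, fs=FS),
                               templates_6s)
        assert np.ptp([p.c_face for p in stream.pairs]) < 1e-9

    def test_short_trial_rejected(self, templates_5s, rng):
        model = small_model(rng, n_channels=2, lags_s=(0.0,))
        seg = EEGSegment(data=rng.standard_normal((256, 2)), fs=FS)
        with pytest.raises(ValueError, match="shorter"):
            stream_scores(model, seg, templates_5s)


def make_stream(pairs_fs):
    pairs = [
        ScorePair(c_face=f, c_spiral=s, window_end=3.0 + 0.25 * i)
        for i, (f, s) in enumerate(pairs_fs)
    ]
    return ScoreStream(pairs=pairs)


class TestDecide:
    def test_face_wins(self):
        stream = make_stream([(0.5, 0.1)] * 6)
        assert decide(stream) == "face"

    def test_spiral_wins(self):
        stream = make_stream([(0.0, 0.2)] * 8)
        assert decide(stream) == "spiral"

    def test_tie_resolves_to_face_and_logs(self, caplog):
        stream = make_stream([(0.3, 0.3)] * 6)
        with caplog.at_level("INFO", logger="cbloop.decoder"):
            assert decide(stream) == "face"
        assert any("tie" in m for m in caplog.messages)

    def test_uses_only_last_n(self):
        pairs = [(0.9, 0.0)] * 6 + [(0.0, 0.4)] * 6
        assert decide(make_stream(pairs)) == "spiral"

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_argmax(self, trial):
        rng = np.random.default_rng(trial)
        vals = rng.uniform(-1, 1, size=(9, 2))
        stream = make_stream([tuple(v) for v in vals])
        expected = "face" if vals[-6:, 0].mean() > vals[-6:, 1].mean() else "spiral"
        if vals[-6:, 0].mean() == vals[-6:, 1].mean():
            expected = "face"
        assert decide(stream) == expected

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError, match="needs"):
            decide(make_stream([(0.1, 0.2)] * 5))


class TestCrossval:
    def test_noiseless_generator_perfect_accuracy(self):
        trials, tpl = noiseless_trials(n_trials=6)
        acc = crossval_accuracy(trials, tpl, lags=default_lags(FS, 0.05),
                                ridge_grid=[1e-4])
        assert acc == 1.0

    def test_pure_noise_chance_level(self):
        # 60 pure-noise trials: accuracy within binomial error of 0.5
        rng = np.random.default_rng(3)
        tpl = make_templates(fs=FS, duration=5.0)
        trials = []
        for i in range(60):
            seg = EEGSegment(data=rng.standard_normal((1280, 4)), fs=FS)
            trials.append((seg, "face" if i % 2 == 0 else "spiral"))
        acc = crossval_accuracy(trials, tpl, lags=np.array([0.0]),
                                ridge_grid=[1.0])
        assert abs(acc - 0.5) < 3 * 0.5 / np.sqrt(60)

    def test_accuracy_monotone_in_gain_ratio(self):
        # 5-point grid of attended/unattended gain ratios, fixed seeds
        tpl = make_templates(fs=FS, duration=5.0)
        accs = []
        for gain in [0.02, 0.05, 0.1, 0.3, 1.0]:
            gen = EEGGenParams(
                n_channels=8, fs_raw=512.0, attended_gain=gain,
                unattended_gain=0.0, noise_sd=1.0, noise_spectrum="white",
                mixing_seed=5,
            )
            trials = []
            for i in range(12):
                label = "face" if i % 2 == 0 else "spiral"
                trace = AttentionTrace(duration=5.0, initial_state=label)
                raw = simulate_trial_eeg(tpl, trace, gen, seed=i)
                trials.append((preprocess_training(raw, fs_out=FS), label))
            accs.append(
                crossval_accuracy(trials, tpl, lags=default_lags(FS, 0.05),
                                  ridge_grid=[1e-2])
            )
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]

    def test_inner_lambda_selection_runs(self):
        trials, tpl = noiseless_trials(n_trials=6)
        acc = crossval_accuracy(
            trials, tpl, lags=default_lags(FS, 0.05),
            ridge_grid=[1e-4, 1e2], inner_folds=3,
        )
        assert acc == 1.0


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        model = small_model(rng)
        model.training_meta["note"] = "unit"
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = BackwardModel.from_json(path)
        np.testing.assert_array_equal(loaded.weights, model.weights)
        np.testing.assert_array_equal(loaded.lags, model.lags)
        assert loaded.fs == model.fs
        assert loaded.training_meta["note"] == "unit"

    def test_invariant_violations_rejected(self, rng):
        with pytest.raises(ValueError):
            BackwardModel(weights=np.zeros((2, 3)), lags=np.array([0.0]),
                          ridge_lambda=0.0, fs=FS)
        with pytest.raises(ValueError):
            BackwardModel(weights=np.zeros((2, 2)),
                          lags=np.array([0.1, 0.0]), ridge_lambda=0.0, fs=FS)
        with pytest.raises(ValueError):
            BackwardModel(weights=np.zeros((2, 1)), lags=np.array([0.0]),
                          ridge_lambda=-1.0, fs=FS)
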