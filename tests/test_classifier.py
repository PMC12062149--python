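"""Two-stage recognition, feature vectors, baselines, and their invariances."""

import numpy as np
import pytest

from htrcca import (
    CandidateSet,
    FeatureMatrix,
    apply_filter_bank,
    cca_scores,
    classify,
    concatenate_filters,
    ehtrcca_classify,
    ensemble_correlation,
    etrca_scores,
    feature_vector,
    matrix_correlation,
    max_canonical_correlation,
    pearson,
    predict_trial,
    stage1,
    stage2,
    subband_weight,
    trca_scores,
)


def feature_oracle(X, n, bank, refs):
    """Independent re-computation of the five fused features for stimulus n."""
    raw = np.zeros((5, bank.n_bands))
    for bi in range(bank.n_bands):
        Xb = apply_filter_bank(X, bank.specs, bank.fs)[bi]
        m = bank.get(n, bi + 1)
        Yn = refs[n]
        raw[0, bi] = max_canonical_correlation(Xb, Yn)
        raw[1, bi] = pearson(m.wa @ Xb, m.wa @ m.template)
        raw[2, bi] = pearson(m.wa @ Xb, m.wb @ Yn)
        raw[3, bi] = pearson(m.wc @ Xb, m.wd @ Yn)
        raw[4, bi] = pearson(m.wc @ Xb, m.wc @ m.template)
    w = np.array([subband_weight(b) for b in range(1, bank.n_bands + 1)])
    return (w[None, :] * raw**2).sum(axis=1)


class TestFeatures:
    def test_matches_independent_oracle(self, trained8):
        bank, refs, _, test, labels = trained8
        for t in (0, 3):
            got = feature_vector(test[t], int(labels[t]), bank, refs)
            want = feature_oracle(test[t], int(labels[t]), bank, refs)
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_matched_stimulus_near_theoretical_maximum(self, trained8):
        bank, refs, _, test, labels = trained8
        cmax = sum(subband_weight(b) for b in range(1, 6))
        f = feature_vector(test[0], int(labels[0]), bank, refs)
        # noise-free: template-route components (2 and 5) hit the fusion
        # ceiling sum_b c_b exactly; reference-route components fall short
        # only in sub-bands above the simulated harmonics
        assert f[1] == pytest.approx(cmax, abs=1e-6)
        assert f[4] == pytest.approx(cmax, abs=1e-6)
        assert np.all(f > 0.6 * cmax)

    def test_noise_trial_scores_below_matched(self, trained8):
        bank, refs, _, test, labels = trained8
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(20):
            noise = rng.standard_normal(test[0].shape)
            fn = feature_vector(noise, int(labels[0]), bank, refs)
            fm = feature_vector(test[0], int(labels[0]), bank, refs)
            wins += fn.sum() < fm.sum()
        assert wins >= 19

    def test_nonnegative(self, trained8):
        bank, refs, _, test, _ = trained8
        f = feature_vector(test[1], 5, bank, refs)
        assert np.all(f >= 0)


class TestStages:
    def test_stage1_noise_free_keeps_truth_in_candidates(self, trained8):
        bank, refs, _, test, labels = trained8
        for t in range(len(test)):
            _, cand = stage1(test[t], bank, refs, seed=0)
            assert int(labels[t]) in cand.indices

    def test_stage1_deterministic(self, trained8):
        bank, refs, _, test, _ = trained8
        _, c1 = stage1(test[0], bank, refs, seed=3)
        _, c2 = stage1(test[0], bank, refs, seed=3)
        np.testing.assert_array_equal(c1.indices, c2.indices)

    def test_two_stimulus_problem_makes_all_stimuli_candidates(self, caplog):
        from conftest import windowed
        from htrcca import (
            EpochSet,
            SimConfig,
            design_subbands,
            fit_model_bank,
            make_reference_bank,
            simulate_epochset,
        )

        ep = simulate_epochset(
            SimConfig(freqs=np.array([9.0, 13.0]), n_blocks=3, snr_db=None,
                      trial_len_s=0.9, seed=21)
        )
        win = windowed(ep, 0.6)
        mask = ep.blocks < 2
        train = EpochSet(
            data=win.data[mask], fs=ep.fs, labels=ep.labels[mask],
            blocks=ep.blocks[mask], freqs=ep.freqs,
            channel_names=ep.channel_names,
        )
        specs = design_subbands(ep.fs, 5)
        refs = make_reference_bank(ep.freqs, ep.fs, train.n_samples, 5)
        bank = fit_model_bank(train, refs, specs)
        X = win.data[ep.blocks == 2][0]
        with caplog.at_level("WARNING", logger="htrcca.classify"):
            _, cand = stage1(X, bank, refs, seed=0)
        assert cand.indices.tolist() == [0, 1]
        assert any("below the clustering minimum" in r.message for r in caplog.records)
        d = classify(X, bank, refs, seed=0)
        assert d.predicted == int(ep.labels[ep.blocks == 2][0])

    def test_stage2_sums_features_into_T(self, trained8):
        bank, refs, _, test, _ = trained8
        feats, cand = stage1(test[0], bank, refs, seed=0)
        d = stage2(test[0], cand, feats, bank)
        np.testing.assert_allclose(
            d.T, feats.values[cand.indices].sum(axis=1), atol=1e-12
        )
        np.testing.assert_allclose(d.C, d.T + d.D, atol=1e-12)
        assert d.predicted in cand.indices

    def test_singleton_candidate_short_circuits(self, trained8):
        bank, refs, _, test, _ = trained8
        feats = FeatureMatrix(values=np.random.default_rng(0).random((8, 5)))
        cand = CandidateSet(
            indices=np.array([5]), h_selected=2, cluster_means=np.array([1.0, 0.1])
        )
        d = stage2(test[0], cand, feats, bank)
        assert d.predicted == 5
        np.testing.assert_array_equal(d.D, [0.0])


class TestClassify:
    def test_noise_free_all_methods_correct(self, trained8):
        bank, refs, specs, test, labels = trained8
        for t in range(0, len(test), 2):
            truth = int(labels[t])
            for method in ("cca", "trca", "etrca", "htrcca", "ehtrcca"):
                assert predict_trial(
                    test[t], method, bank, refs, specs=specs, fs=250.0, seed=0
                ) == truth

    def test_scale_invariance_of_decision(self, trained8):
        bank, refs, _, test, _ = trained8
        d1 = classify(test[2], bank, refs, seed=1)
        d2 = classify(3.7 * test[2], bank, refs, seed=1)
        assert d1.predicted == d2.predicted
        np.testing.assert_allclose(d1.C, d2.C, atol=1e-8)

    def test_repeat_run_identical(self, trained8):
        bank, refs, _, test, _ = trained8
        a = [classify(test[t], bank, refs, seed=4).predicted for t in range(4)]
        b = [classify(test[t], bank, refs, seed=4).predicted for t in range(4)]
        assert a == b

    def test_candidates_outscore_rest_on_average(self, trained8):
        bank, refs, _, test, _ = trained8
        feats, cand = stage1(test[1], bank, refs, seed=0)
        rest = np.setdiff1d(np.arange(8), cand.indices)
        if rest.size:
            assert feats.values[cand.indices].mean() > feats.values[rest].mean()


class TestBaselines:
    def test_trca_single_band_reduces_to_unbanked(self, ep8):
        from conftest import windowed
        from htrcca import EpochSet, design_subbands, fit_model_bank, make_reference_bank

        win = windowed(ep8, 1.0)
        mask = ep8.blocks < 2
        train = EpochSet(
            data=win.data[mask], fs=ep8.fs, labels=ep8.labels[mask],
            blocks=ep8.blocks[mask], freqs=ep8.freqs,
            channel_names=ep8.channel_names,
        )
        specs = design_subbands(ep8.fs, 1)
        refs = make_reference_bank(ep8.freqs, ep8.fs, train.n_samples, 5)
        bank = fit_model_bank(train, refs, specs)
        X = win.data[ep8.blocks == 2][0]
        fused = trca_scores(X, bank)
        Xb = apply_filter_bank(X, specs, ep8.fs)[0]
        raw = np.array(
            [
                pearson(bank.get(n, 1).wt @ Xb, bank.get(n, 1).wt @ bank.get(n, 1).template)
                for n in range(8)
            ]
        )
        assert int(np.argmax(fused)) == int(np.argmax(raw))

    def test_single_column_ensemble_equals_trca_score(self, trained8):
        bank, _, _, test, _ = trained8
        Xb = apply_filter_bank(test[0], bank.specs, bank.fs)[0]
        m = bank.get(2, 1)
        W = concatenate_filters(bank, [2], band=1)
        ens = matrix_correlation(Xb.T @ W, m.template.T @ W)
        direct = pearson(m.wt @ Xb, m.wt @ m.template)
        assert ens == pytest.approx(direct, abs=1e-12)

    def test_etrca_matches_ensemble_correlation(self, trained8):
        bank, _, _, test, _ = trained8
        scores = etrca_scores(test[0], bank)
        for n in (0, 4):
            assert scores[n] == pytest.approx(
                ensemble_correlation(test[0], n, bank), abs=1e-10
            )

    def test_ehtrcca_with_all_candidates_uses_full_ensemble(self, trained8):
        bank, refs, _, test, _ = trained8
        feats = FeatureMatrix(values=np.tile(np.arange(8.0)[:, None], (1, 5)))
        cand = CandidateSet(
            indices=np.arange(8), h_selected=1, cluster_means=np.array([1.0])
        )
        d = stage2(test[0], cand, feats, bank, ensemble=np.arange(8))
        np.testing.assert_allclose(d.D, etrca_scores(test[0], bank), atol=1e-10)

    def test_cca_scores_runs_without_training(self, trained8, ep8):
        _, refs, specs, test, labels = trained8
        s = cca_scores(test[0], refs, specs, ep8.fs)
        assert int(np.argmax(s)) == int(labels[0])

    def test_unknown_method_rejected(self, trained8):
        bank, refs, _, test, _ = trained8
        with pytest.raises(ValueError, match="unknown method"):
            predict_trial(test[0], "fbcca", bank, refs)
        with pytest.raises(ValueError, match="model bank"):
            predict_trial(test[0], "trca", None, refs)
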