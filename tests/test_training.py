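"""Spatial-filter training: CCA filter pairs, TRCA eigenproblem, model banks."""

import numpy as np
import pytest

from htrcca import (
    build_template,
    cca,
    concatenate_filters,
    fit_model_bank,
    make_reference,
    pearson,
    train_template_filters,
    train_trca_filter,
    train_trial_filters,
)


class TestTemplate:
    def test_single_trial_is_its_own_template(self):
        x = np.random.default_rng(0).standard_normal((1, 3, 20))
        np.testing.assert_array_equal(build_template(x), x[0])

    def test_opposite_trials_cancel(self):
        x = np.random.default_rng(1).standard_normal((3, 20))
        np.testing.assert_allclose(
            build_template(np.stack([x, -x])), 0.0, atol=1e-15
        )

    def test_mean_of_constants(self):
        trials = np.stack([np.full((2, 5), v) for v in (1.0, 2.0, 3.0)])
        np.testing.assert_array_equal(build_template(trials), np.full((2, 5), 2.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_template(np.empty((0, 2, 5)))


def toy_template(seed=0, nc=4, ns=125, fn=10.0, fs=250.0):
    rng = np.random.default_rng(seed)
    Y = make_reference(fn, fs, ns, 2)
    mix = rng.standard_normal((nc, 4))
    return mix @ Y + 0.05 * rng.standard_normal((nc, ns)), Y


class TestTemplateFilters:
    def test_tiling_invariance_in_trial_count(self):
        template, Y = toy_template()
        results = [train_template_filters(template, nt, Y) for nt in (1, 2, 5)]
        for wa, wb in results[1:]:
            np.testing.assert_allclose(wa, results[0][0], atol=1e-10)
            np.testing.assert_allclose(wb, results[0][1], atol=1e-10)

    def test_noise_free_projection_correlates(self):
        rng = np.random.default_rng(3)
        Y = make_reference(12.0, 250.0, 250, 3)
        template = rng.standard_normal((5, 6)) @ Y  # pure SSVEP mixture
        wa, wb = train_template_filters(template, 2, Y)
        assert pearson(wa @ template, wb @ Y) >= 0.999

    def test_reduces_to_plain_cca_of_template(self):
        template, Y = toy_template(seed=4)
        wa, wb = train_template_filters(template, 3, Y)
        res = cca(template, Y)
        np.testing.assert_allclose(wa, res.Wx[:, 0], atol=1e-8)
        np.testing.assert_allclose(wb, res.Wy[:, 0], atol=1e-8)

    def test_degenerate_template_rejected(self):
        Y = make_reference(10.0, 250.0, 50, 1)
        with pytest.raises(ValueError, match="degenerate"):
            train_template_filters(np.ones((3, 50)), 2, Y)


class TestTrialFilters:
    def test_single_trial_equals_template_filters(self):
        template, Y = toy_template(seed=5)
        wa, wb = train_template_filters(template, 1, Y)
        wc, wd = train_trial_filters(template, Y)
        np.testing.assert_allclose(wc, wa, atol=1e-10)
        np.testing.assert_allclose(wd, wb, atol=1e-10)

    def test_repeated_identical_trials_match_single(self):
        template, Y = toy_template(seed=6)
        wc1, wd1 = train_trial_filters(template, Y)
        wc3, wd3 = train_trial_filters(
            np.tile(template, (1, 3)), np.tile(Y, (1, 3))
        )
        np.testing.assert_allclose(wc3, wc1, atol=1e-10)
        np.testing.assert_allclose(wd3, wd1, atol=1e-10)


def trca_toy(seed, nt=10, ns=250, fs=250.0, noise=1.0):
    """Channel 1 carries a common 12 Hz sinusoid, channel 2 independent noise."""
    rng = np.random.default_rng(seed)
    common = np.sin(2 * np.pi * 12.0 * np.arange(ns) / fs)
    trials = np.stack(
        [
            np.stack([common + 0.1 * rng.standard_normal(ns),
                      noise * rng.standard_normal(ns)])
            for _ in range(nt)
        ]
    )
    return trials, common


class TestTrca:
    def test_recovers_common_component(self):
        corrs = []
        for seed in range(5):
            trials, common = trca_toy(seed)
            wt = train_trca_filter(trials)
            corrs.extend(abs(pearson(wt @ t, common)) for t in trials)
        assert np.mean(corrs) >= 0.95

    def test_component_invariant_to_premixing(self):
        trials, _ = trca_toy(11, nt=8)
        rng = np.random.default_rng(12)
        A = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        mixed = np.einsum("ij,tjs->tis", A, trials)
        w0, w1 = train_trca_filter(trials), train_trca_filter(mixed)
        c = abs(pearson(w0 @ trials[0], w1 @ mixed[0]))
        assert c >= 0.999

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            train_trca_filter(np.zeros((1, 3, 50)) + np.random.rand(1, 3, 50))

    def test_identical_trials_warn_degenerate(self, caplog):
        x = np.random.default_rng(13).standard_normal((3, 100))
        with caplog.at_level("WARNING", logger="htrcca.training"):
            wt = train_trca_filter(np.stack([x, x]))
        assert np.isfinite(wt).all()
        assert any("degenerate" in r.message for r in caplog.records)

    def test_rayleigh_quotient_maximality(self):
        trials, _ = trca_toy(14, nt=6)
        centered = trials - trials.mean(axis=2, keepdims=True)
        Q = sum(t @ t.T for t in centered)
        tot = sum(centered)
        S = tot @ tot.T - Q

        def objective(w):
            return (w @ S @ w) / (w @ Q @ w)

        wt = train_trca_filter(trials)
        rng = np.random.default_rng(15)
        best_random = max(
            objective(v / np.linalg.norm(v))
            for v in rng.standard_normal((100, trials.shape[1]))
        )
        assert objective(wt) >= best_random - 1e-10

    def test_filter_invariant_to_global_rescaling(self):
        trials, _ = trca_toy(16, nt=5)
        np.testing.assert_allclose(
            train_trca_filter(trials), train_trca_filter(1e3 * trials), atol=1e-8
        )


class TestModelBank:
    def test_grid_size_and_determinism(self, trained8):
        bank, _, specs, _, _ = trained8
        assert bank.n_stimuli == 8 and bank.n_bands == 5

    def test_refit_is_bit_identical(self, ep8, trained8):
        from conftest import windowed
        from htrcca import EpochSet, make_reference_bank

        bank, refs, specs, _, _ = trained8
        win = windowed(ep8, 1.0)
        mask = ep8.blocks < 2
        train = EpochSet(
            data=win.data[mask], fs=ep8.fs, labels=ep8.labels[mask],
            blocks=ep8.blocks[mask], freqs=ep8.freqs,
            channel_names=ep8.channel_names,
        )
        bank2 = fit_model_bank(train, refs, specs)
        for n in range(8):
            np.testing.assert_array_equal(bank.get(n, 1).wt, bank2.get(n, 1).wt)
            np.testing.assert_array_equal(bank.get(n, 3).wa, bank2.get(n, 3).wa)

    def test_noise_free_templates_track_references(self, trained8):
        # templates are band-filtered while references are analytic, so the
        # zero-phase filter's edge transients cap the correlation just below 1
        bank, refs, _, _, _ = trained8
        for n in range(8):
            m = bank.get(n, 1)
            assert pearson(m.wa @ m.template, m.wb @ refs[n]) >= 0.995

    def test_missing_stimulus_listed_in_error(self, ep8, trained8):
        from conftest import windowed
        from htrcca import EpochSet

        _, refs, specs, _, _ = trained8
        win = windowed(ep8, 1.0)
        mask = (ep8.blocks < 2) & (ep8.labels != 3)
        train = EpochSet(
            data=win.data[mask], fs=ep8.fs, labels=ep8.labels[mask],
            blocks=ep8.blocks[mask], freqs=ep8.freqs,
            channel_names=ep8.channel_names,
        )
        with pytest.raises(ValueError, match=r"\[3\]"):
            fit_model_bank(train, refs, specs)


class TestConcatenate:
    def test_column_order_follows_indices(self, trained8):
        bank, _, _, _, _ = trained8
        W = concatenate_filters(bank, [2, 0, 5], band=1)
        np.testing.assert_array_equal(W[:, 0], bank.get(2, 1).wt)
        np.testing.assert_array_equal(W[:, 1], bank.get(0, 1).wt)
        assert W.shape == (bank.get(0, 1).wt.size, 3)

    def test_full_and_singleton_ensembles(self, trained8):
        bank, _, _, _, _ = trained8
        assert concatenate_filters(bank, list(range(8)), band=2).shape[1] == 8
        w = concatenate_filters(bank, [4], band=2)
        np.testing.assert_array_equal(w[:, 0], bank.get(4, 2).wt)

    def test_out_of_range_index_rejected(self, trained8):
        bank, _, _, _, _ = trained8
        with pytest.raises(ValueError, match="out of range"):
            concatenate_filters(bank, [8], band=1)
        with pytest.raises(ValueError):
            concatenate_filters(bank, [], band=1)
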