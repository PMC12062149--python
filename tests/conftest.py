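"""Shared fixtures: small synthetic epoch sets and pre-trained model banks."""

import numpy as np
import pytest

from htrcca import (
    SimConfig,
    design_subbands,
    extract_epoch,
    fit_model_bank,
    make_fixture_suite,
    make_reference_bank,
    simulate_epochset,
)
from htrcca.signal_model import EpochSet


def windowed(epochs: EpochSet, window_s: float) -> EpochSet:
    """Cut the analysis window out of every raw trial of an epoch set."""
    data = np.stack(
        [
            extract_epoch(epochs.data[t], epochs.fs, epochs.latency_s, window_s)
            for t in range(epochs.n_trials)
        ]
    )
    return EpochSet(
        data=data,
        fs=epochs.fs,
        labels=epochs.labels,
        blocks=epochs.blocks,
        freqs=epochs.freqs,
        channel_names=epochs.channel_names,
        latency_s=0.0,
    )


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def ep8(suite):
    """Noise-free 8-class set, 3 blocks."""
    return suite["noisefree8"]


@pytest.fixture(scope="session")
def trained8(ep8):
    """(bank, references, specs, test-trial windows, test labels) for ep8.

    Trained on blocks 0-1 with a 1 s window and Nb=5, Nh=5; block 2 held out.
    """
    window_s = 1.0
    win = windowed(ep8, window_s)
    train_mask = ep8.blocks < 2
    train = EpochSet(
        data=win.data[train_mask],
        fs=ep8.fs,
        labels=ep8.labels[train_mask],
        blocks=ep8.blocks[train_mask],
        freqs=ep8.freqs,
        channel_names=ep8.channel_names,
        latency_s=0.0,
    )
    specs = design_subbands(ep8.fs, 5)
    refs = make_reference_bank(ep8.freqs, ep8.fs, train.n_samples, 5)
    bank = fit_model_bank(train, refs, specs)
    test_mask = ep8.blocks == 2
    return bank, refs, specs, win.data[test_mask], ep8.labels[test_mask]


@pytest.fixture(scope="session")
def tiny_noisy():
    """4-class, 4-channel, 4-block moderate-noise set for cheap harness tests."""
    return simulate_epochset(
        SimConfig(
            freqs=np.array([8.0, 10.0, 12.0, 14.0]),
            n_channels=4,
            n_blocks=4,
            trial_len_s=0.9,
            snr_db=-5.0,
            seed=7,
        )
    )
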