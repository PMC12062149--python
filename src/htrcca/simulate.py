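"""Synthetic SSVEP generator shaped like the public 40-target benchmarks.

Each trial is a harmonic series at its stimulus frequency — amplitudes
decaying as 1/h, a per-stimulus phase offset stepping by 0.35*pi, onset
delayed by the visual latency — mixed into the channels through a fixed,
seeded gain matrix with occipital-dominant weights, plus independent
pink (1/f) and white noise per channel scaled to a target SNR.  The SNR is
defined in the 6–90 Hz analysis band (the band the recognizers actually
see), measured over the post-latency portion of the trial.

The clean and noise components are retained on the returned
:class:`EpochSet` so the realized SNR can be audited.  One trial is
generated per (block, stimulus) pair, matching the block structure of the
benchmark recordings.  Fixed seed implies bit-exact reproducibility.

What this emulates — stable per-stimulus amplitude/phase across trials (the
structure TRCA exploits), frequency-tagged harmonics, occipital dominance,
1/f background.  What it does not — trial-to-trial amplitude drift,
artifacts, inter-subject variability, volume-conduction correlations in the
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .filter_bank import _design_sos, design_subbands
from .signal_model import EpochSet, round_half_up

__all__ = ["SimConfig", "simulate_epochset", "realized_snr", "make_fixture_suite"]

OCCIPITAL_CHANNELS = ["Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2"]


def _default_freqs() -> np.ndarray:
    return np.round(8.0 + 0.2 * np.arange(40), 10)


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the 40-target benchmark geometry."""

    freqs: np.ndarray = field(default_factory=_default_freqs)
    phase_step_pi: float = 0.35  # phase of stimulus n is 0.35*pi*n (wrapped)
    n_channels: int = 9
    channel_names: list[str] | None = None
    fs: float = 250.0
    n_blocks: int = 6
    trial_len_s: float = 1.5
    latency_s: float = 0.14
    # five observable harmonics with 1/h decay, mirroring the Nh=5 analysis
    # convention; the 5th harmonic of 15.8 Hz (79 Hz) stays inside 6-90 Hz,
    # so every sub-band of the filter bank carries genuine signal
    harmonic_amplitudes: tuple[float, ...] = (1.0, 1 / 2, 1 / 3, 1 / 4, 1 / 5)
    occipital_gain: float = 3.0  # signal gain of occipital over other channels
    mixing_jitter: float = 0.3  # relative spread of per-harmonic channel gains
    pink_exponent: float = 1.0
    white_fraction: float = 0.2  # white-noise amplitude relative to pink
    snr_db: float | None = -10.0  # None disables noise entirely
    seed: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        nh = len(self.harmonic_amplitudes)
        if nh * self.freqs.max() >= self.fs / 2:
            raise ValueError("highest simulated harmonic reaches Nyquist")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.channel_names is None:
            base = list(OCCIPITAL_CHANNELS)
            while len(base) < self.n_channels:
                base.append(f"CH{len(base) + 1}")
            self.channel_names = base[: self.n_channels]


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^alpha noise via spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec /= f ** (exponent / 2)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def _inband_power(x: np.ndarray, sos: np.ndarray, start: int) -> float:
    """Mean power of the 6-90 Hz component of x over samples [start:]."""
    y = sp_signal.sosfiltfilt(sos, x, axis=-1)
    return float(np.mean(y[..., start:] ** 2))


def simulate_epochset(config: SimConfig) -> EpochSet:
    """Generate one trial per (block, stimulus) under the given settings."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nf = len(cfg.freqs)
    nc = cfg.n_channels
    n_raw = round_half_up(cfg.trial_len_s * cfg.fs)
    onset = round_half_up(cfg.latency_s * cfg.fs)
    if onset >= n_raw:
        raise ValueError("latency exceeds the trial length")
    t = np.arange(n_raw) / cfg.fs
    active = t >= cfg.latency_s

    # occipital-dominant channel gain profile with per-harmonic jitter,
    # fixed for the whole dataset so filters see a stable mixture
    n_occ = min(nc, len(OCCIPITAL_CHANNELS))
    base = np.full(nc, 1.0 / cfg.occipital_gain)
    base[:n_occ] = 1.0
    nh = len(cfg.harmonic_amplitudes)
    gains = base[None, :] * (
        1.0 + cfg.mixing_jitter * rng.standard_normal((nh, nc))
    )

    # clean per-stimulus multi-channel signal, shared by all blocks
    clean_stim = np.zeros((nf, nc, n_raw))
    for n in range(nf):
        phase = (cfg.phase_step_pi * np.pi * n) % (2 * np.pi)
        for h in range(1, nh + 1):
            wave = np.where(
                active,
                cfg.harmonic_amplitudes[h - 1]
                * np.sin(2 * np.pi * h * cfg.freqs[n] * (t - cfg.latency_s)
                         + h * phase),
                0.0,
            )
            clean_stim[n] += gains[h - 1][:, None] * wave[None, :]
        if not np.any(clean_stim[n]):
            raise ValueError(f"stimulus {n}: zero clean signal, SNR undefined")

    sos = _design_sos(design_subbands(cfg.fs, 1)[0], cfg.fs)

    n_trials = cfg.n_blocks * nf
    data = np.empty((n_trials, nc, n_raw))
    clean = np.empty_like(data)
    noise = np.zeros_like(data)
    labels = np.empty(n_trials, dtype=int)
    blocks = np.empty(n_trials, dtype=int)
    i = 0
    for b in range(cfg.n_blocks):
        for n in range(nf):
            labels[i] = n
            blocks[i] = b
            clean[i] = clean_stim[n]
            if cfg.snr_db is None:
                data[i] = clean_stim[n]
            else:
                raw_noise = np.stack(
                    [
                        _pink_noise(rng, n_raw, cfg.pink_exponent)
                        + cfg.white_fraction * rng.standard_normal(n_raw)
                        for _ in range(nc)
                    ]
                )
                ps = _inband_power(clean_stim[n], sos, onset)
                pn = _inband_power(raw_noise, sos, onset)
                scale = np.sqrt(ps / (pn * 10 ** (cfg.snr_db / 10)))
                noise[i] = scale * raw_noise
                data[i] = clean_stim[n] + noise[i]
            i += 1
    return EpochSet(
        data=data,
        fs=cfg.fs,
        labels=labels,
        blocks=blocks,
        freqs=cfg.freqs,
        channel_names=list(cfg.channel_names),
        latency_s=cfg.latency_s,
        clean=clean,
        noise=noise if cfg.snr_db is not None else np.zeros_like(data),
    )


def realized_snr(epochs: EpochSet, config: SimConfig) -> np.ndarray:
    """Per-trial in-band SNR in dB from the stored clean/noise components."""
    if epochs.clean is None or epochs.noise is None:
        raise ValueError("epoch set carries no simulation components")
    sos = _design_sos(design_subbands(epochs.fs, 1)[0], epochs.fs)
    onset = round_half_up(config.latency_s * epochs.fs)
    out = np.empty(epochs.n_trials)
    for i in range(epochs.n_trials):
        ps = _inband_power(epochs.clean[i], sos, onset)
        pn = _inband_power(epochs.noise[i], sos, onset)
        out[i] = np.inf if pn == 0 else 10 * np.log10(ps / pn)
    return out


def make_fixture_suite(seed: int = 0) -> dict[str, EpochSet]:
    """Canonical small test fixtures, deterministic in the seed.

    ``noisefree8``/``noisefree40`` — clean 8- and 40-class sets (3 blocks);
    ``moderate40`` — 40-class set at the default -10 dB in-band SNR;
    ``identical`` — 2-block clean set whose trials repeat exactly;
    ``zerochan`` — moderate 8-class set with its last channel zeroed.
    """
    eight = _default_freqs()[::5]  # 8 frequencies spread over 8-15.8 Hz
    fixtures = {
        "noisefree8": simulate_epochset(
            SimConfig(freqs=eight, n_blocks=3, snr_db=None, trial_len_s=1.2,
                      seed=seed)
        ),
        "noisefree40": simulate_epochset(
            SimConfig(n_blocks=3, snr_db=None, trial_len_s=1.2, seed=seed + 1)
        ),
        "moderate40": simulate_epochset(
            SimConfig(n_blocks=3, trial_len_s=1.2, seed=seed + 2)
        ),
        "identical": simulate_epochset(
            SimConfig(freqs=eight, n_blocks=2, snr_db=None, trial_len_s=1.2,
                      seed=seed + 3)
        ),
    }
    zc = simulate_epochset(
        SimConfig(freqs=eight, n_blocks=3, trial_len_s=1.2, seed=seed + 4)
    )
    zc.data[:, -1, :] = 0.0
    fixtures["zerochan"] = zc
    return fixtures
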