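"""Core data containers and sine–cosine reference construction.

SSVEP recognizers compare multi-channel EEG epochs against artificial
reference matrices built from sines and cosines at each stimulus frequency
and its harmonics.  This module holds the epoch container (:class:`EpochSet`),
the per-stimulus reference bank (:class:`ReferenceBank`), and the epoch
windowing used to cut analysis windows out of raw trials after the visual
latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpochSet",
    "ReferenceBank",
    "make_reference",
    "make_reference_bank",
    "extract_epoch",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for positive x: up).

    Used for converting fractional second offsets (latency, window length)
    into sample counts, e.g. 0.13 s x 250 Hz = 32.5 -> 33.
    """
    return int(math.floor(x + 0.5))


@dataclass
class EpochSet:
    """Epoched multi-channel EEG trials with labels and block structure.

    Parameters
    ----------
    data : ndarray, shape (n_trials, Nc, Ns)
        Trial data in volts (arbitrary scale; all downstream correlations
        are scale-invariant).
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (n_trials,)
        Stimulus index per trial, in ``0..Nf-1``.
    blocks : ndarray of int, shape (n_trials,)
        Recording-block index per trial.
    freqs : ndarray of float, shape (Nf,)
        Stimulus frequency table in Hz.
    channel_names : list of str
        Ordered channel labels, length Nc.
    latency_s : float
        Visual-latency offset applied at epoch extraction, seconds.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    blocks: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]
    latency_s: float = 0.0
    # optional simulator provenance (clean/noise components), same shape as data
    clean: np.ndarray | None = field(default=None, repr=False)
    noise: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=int)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be [n_trials x Nc x Ns]")
        n, nc, ns = self.data.shape
        if ns < 2:
            raise ValueError("epochs need Ns >= 2 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels.shape != (n,) or self.blocks.shape != (n,):
            raise ValueError("labels/blocks must have one entry per trial")
        if self.labels.size and self.labels.max() >= len(self.freqs):
            raise ValueError("label index exceeds frequency table length")
        if len(self.channel_names) != nc:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {nc} channels"
            )
        pairs = list(zip(self.blocks.tolist(), self.labels.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("every (block, stimulus) pair may occur at most once")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_stimuli(self) -> int:
        return len(self.freqs)

    def select_channels(self, index: list[int]) -> "EpochSet":
        """Return a copy restricted to the given channel indices (order kept)."""
        return EpochSet(
            data=self.data[:, index, :].copy(),
            fs=self.fs,
            labels=self.labels.copy(),
            blocks=self.blocks.copy(),
            freqs=self.freqs.copy(),
            channel_names=[self.channel_names[i] for i in index],
            latency_s=self.latency_s,
            clean=None if self.clean is None else self.clean[:, index, :].copy(),
            noise=None if self.noise is None else self.noise[:, index, :].copy(),
        )


@dataclass
class ReferenceBank:
    """Per-stimulus sine–cosine reference matrices Y_n, shape (Nf, 2*Nh, Ns)."""

    Y: np.ndarray
    Nh: int
    freqs: np.ndarray
    fs: float
    Ns: int

    def __getitem__(self, n: int) -> np.ndarray:
        return self.Y[n]

    @property
    def n_stimuli(self) -> int:
        return self.Y.shape[0]


def make_reference(fn: float, fs: float, Ns: int, Nh: int) -> np.ndarray:
    """Build the sine–cosine reference matrix for one stimulus frequency.

    Row ``2h-2`` is ``sin(2*pi*h*fn*t)`` and row ``2h-1`` is
    ``cos(2*pi*h*fn*t)`` for harmonics ``h = 1..Nh``, sampled at
    ``t = 1/fs, 2/fs, ..., Ns/fs`` (the sample index starts at one, matching
    the phase convention of the classical CCA recognizer).

    Returns
    -------
    ndarray, shape (2*Nh, Ns)
    """
    if fn <= 0:
        raise ValueError("stimulus frequency must be positive")
    if Ns < 1:
        raise ValueError("Ns must be >= 1")
    if Nh < 1:
        raise ValueError("Nh must be >= 1")
    if Nh * fn >= fs / 2:
        raise ValueError(
            f"harmonic {Nh} of {fn} Hz is {Nh * fn} Hz, at or above the "
            f"Nyquist frequency {fs / 2} Hz"
        )
    t = np.arange(1, Ns + 1) / fs
    Y = np.empty((2 * Nh, Ns))
    for h in range(1, Nh + 1):
        ang = 2 * np.pi * h * fn * t
        Y[2 * h - 2] = np.sin(ang)
        Y[2 * h - 1] = np.cos(ang)
    return Y


def make_reference_bank(
    freqs: np.ndarray, fs: float, Ns: int, Nh: int
) -> ReferenceBank:
    """Build reference matrices for every stimulus frequency.

    Raises on duplicate frequencies: stimuli must remain distinguishable.
    """
    freqs = np.asarray(freqs, dtype=float)
    if len(np.unique(freqs)) != len(freqs):
        raise ValueError("duplicate stimulus frequencies in table")
    Y = np.stack([make_reference(f, fs, Ns, Nh) for f in freqs])
    return ReferenceBank(Y=Y, Nh=Nh, freqs=freqs, fs=fs, Ns=Ns)


def extract_epoch(
    raw: np.ndarray, fs: float, latency_s: float, window_s: float
) -> np.ndarray:
    """Cut the analysis window ``[latency, latency + d)`` out of a raw trial.

    Parameters
    ----------
    raw : ndarray, shape (Nc, n_raw)
        One raw trial, time axis last; sample 0 is stimulus onset.
    latency_s : float
        Visual latency in seconds; window start = round(latency_s * fs)
        (half-up rounding for fractional sample offsets).
    window_s : float
        Window length d in seconds; Ns = round(d * fs).

    Returns
    -------
    ndarray, shape (Nc, Ns)
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw trial must be [Nc x n_raw]")
    start = round_half_up(latency_s * fs)
    ns = round_half_up(window_s * fs)
    stop = start + ns
    if start < 0:
        raise ValueError(f"window start {start} is negative")
    if stop > raw.shape[1]:
        raise ValueError(
            f"window [{start}, {stop}) exceeds the trial length {raw.shape[1]}"
        )
    return raw[:, start:stop].copy()
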