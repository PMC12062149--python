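"""Chebyshev Type-I sub-band decomposition and weighted feature fusion.

SSVEP responses carry information at the stimulus fundamental and its
harmonics.  A bank of band-pass filters with staggered lower edges isolates
successively higher harmonic content; per-sub-band correlation features are
then fused by a weighted sum of their squares, with weights decaying over
sub-band index b as ``c_b = b^-1.25 + 0.25``.

The bank uses the standard five-band edge table: lower passband/stopband
edges [6/4, 14/10, 22/16, 30/24, 38/32] Hz and common upper edges 90/100 Hz.
Filters are applied forward-backward (zero phase).  Reference sinusoids are
analytic and are never band-filtered; only EEG epochs pass through the bank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SubbandSpec",
    "SubbandStack",
    "design_subbands",
    "apply_filter_bank",
    "subband_weight",
    "combine_subbands",
    "SUBBAND_EDGES_HZ",
]

# (passband_lo, stopband_lo) per sub-band; upper edges are 90/100 Hz.
SUBBAND_EDGES_HZ: list[tuple[float, float]] = [
    (6.0, 4.0),
    (14.0, 10.0),
    (22.0, 16.0),
    (30.0, 24.0),
    (38.0, 32.0),
]

#: passband ripple used for the Chebyshev design, dB (one-way).  The filter
#: order comes from cheb1ord at 3 dB passband / 40 dB stopband tolerances,
#: then the filter is designed at this smaller ripple so that in-band tones
#: survive forward-backward application essentially unattenuated.
DEFAULT_RIPPLE_DB = 0.5
DEFAULT_GPASS_DB = 3.0
DEFAULT_GSTOP_DB = 40.0


@dataclass(frozen=True)
class SubbandSpec:
    """Band-pass design spec for one sub-band of the filter bank."""

    b: int  # 1-based sub-band index
    passband_lo: float
    stopband_lo: float
    passband_hi: float
    stopband_hi: float
    passband_ripple: float
    stopband_atten: float

    def __post_init__(self) -> None:
        if not (
            self.stopband_lo < self.passband_lo < self.passband_hi < self.stopband_hi
        ):
            raise ValueError(f"sub-band {self.b}: edges out of order")


@dataclass
class SubbandStack:
    """One epoch decomposed into Nb sub-band copies, shape (Nb, Nc, Ns)."""

    data: np.ndarray
    specs: list[SubbandSpec]

    def __getitem__(self, b: int) -> np.ndarray:
        return self.data[b]

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]


def design_subbands(
    fs: float,
    Nb: int,
    ripple_db: float = DEFAULT_RIPPLE_DB,
    gstop_db: float = DEFAULT_GSTOP_DB,
) -> list[SubbandSpec]:
    """Build the first ``Nb`` sub-band specs of the five-band edge table.

    If the 90/100 Hz upper edges sit at or above Nyquist they are clipped to
    0.9/0.95 of Nyquist with a warning (only relevant below fs = 200 Hz).
    """
    if not 1 <= Nb <= len(SUBBAND_EDGES_HZ):
        raise ValueError(f"Nb must be in 1..{len(SUBBAND_EDGES_HZ)}, got {Nb}")
    hi_pass, hi_stop = 90.0, 100.0
    nyq = fs / 2
    if nyq <= hi_stop:
        hi_pass, hi_stop = 0.9 * nyq, 0.95 * nyq
        logger.warning(
            "upper band edges clipped to %.1f/%.1f Hz (Nyquist %.1f Hz)",
            hi_pass,
            hi_stop,
            nyq,
        )
    return [
        SubbandSpec(
            b=b,
            passband_lo=pl,
            stopband_lo=sl,
            passband_hi=hi_pass,
            stopband_hi=hi_stop,
            passband_ripple=ripple_db,
            stopband_atten=gstop_db,
        )
        for b, (pl, sl) in enumerate(SUBBAND_EDGES_HZ[:Nb], start=1)
    ]


@lru_cache(maxsize=64)
def _design_sos(spec: SubbandSpec, fs: float) -> np.ndarray:
    nyq = fs / 2
    wp = [spec.passband_lo / nyq, spec.passband_hi / nyq]
    ws = [spec.stopband_lo / nyq, spec.stopband_hi / nyq]
    order, _ = signal.cheb1ord(wp, ws, DEFAULT_GPASS_DB, spec.stopband_atten)
    return signal.cheby1(
        order, spec.passband_ripple, wp, btype="bandpass", output="sos"
    )


def apply_filter_bank(
    X: np.ndarray, specs: list[SubbandSpec], fs: float
) -> SubbandStack:
    """Zero-phase band-pass one epoch through every sub-band.

    Forward-backward filtering (``sosfiltfilt``) with odd-reflect padding;
    input must be longer than the padding transient.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be [Nc x Ns]")
    out = np.empty((len(specs),) + X.shape)
    for i, spec in enumerate(specs):
        sos = _design_sos(spec, fs)
        # sosfiltfilt default padlen = 3 * (2 * n_sections + 1) per its docs
        padlen = 3 * (2 * sos.shape[0] + 1)
        if X.shape[1] <= padlen:
            raise ValueError(
                f"epoch of {X.shape[1]} samples is too short for zero-phase "
                f"filtering in sub-band {spec.b} (needs > {padlen} samples)"
            )
        out[i] = signal.sosfiltfilt(sos, X, axis=-1)
    return SubbandStack(data=out, specs=list(specs))


def subband_weight(b: int) -> float:
    """Fusion weight ``c_b = b^-1.25 + 0.25`` for 1-based sub-band index b."""
    if b < 1 or int(b) != b:
        raise ValueError("sub-band index must be a positive integer")
    return float(b) ** -1.25 + 0.25


def combine_subbands(features: np.ndarray) -> float:
    """Fuse per-sub-band features: weighted sum of squares over bands.

    ``rho = sum_b c_b * r_b**2`` — non-negative, invariant to per-band sign.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    weights = np.array([subband_weight(b) for b in range(1, features.shape[0] + 1)])
    return float(np.sum(weights * features**2))
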