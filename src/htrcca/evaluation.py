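"""Leave-one-block-out evaluation, accuracy, information transfer rate, sweeps.

Recognition performance is estimated by leave-one-block-out (LOBO)
cross-validation: with B recording blocks, each block serves once as the
test set while the remaining B-1 blocks train the model bank.  Accuracy is
the fraction of correctly recognized test epochs; the information transfer
rate (ITR) converts accuracy P, alphabet size Nf and selection time Tw into
bits per minute:

    ITR = [log2 Nf + P log2 P + (1-P) log2((1-P)/(Nf-1))] * 60 / (Tw + Tg)

with Tg an optional gaze-shift interval (0 by default).  Sweep grids over
training-trial count Nt, window length Tw, channel count Nc and sub-band
count Nb re-window, re-select and re-bank the same epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import METHODS, predict_trial
from .clustering import DEFAULT_GMM_RESTARTS, DEFAULT_H_RANGE
from .filter_bank import apply_filter_bank, design_subbands
from .signal_model import EpochSet, extract_epoch, make_reference_bank, round_half_up
from .training import fit_model_bank

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "accuracy", "itr", "leave_one_block_out", "sweep"]

DEFAULT_NH = 5
DEFAULT_NB = 5


@dataclass
class EvalResult:
    """Per-fold LOBO outcomes plus the sweep coordinates that produced them."""

    method: str
    fold_blocks: list[int]
    predictions: list[np.ndarray]
    truths: list[np.ndarray]
    fold_accuracy: np.ndarray
    fold_itr: np.ndarray
    n_stimuli: int
    window_s: float
    n_train: int
    n_channels: int
    n_bands: int
    seed: int
    gaze_shift_s: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def mean_itr(self) -> float:
        return float(self.fold_itr.mean())

    def to_frame(self) -> pd.DataFrame:
        """One row per fold: method, Nt, Tw, Nc, Nb, seed, fold, accuracy, ITR."""
        return pd.DataFrame(
            {
                "method": self.method,
                "Nt": self.n_train,
                "Tw": self.window_s,
                "Nc": self.n_channels,
                "Nb": self.n_bands,
                "seed": self.seed,
                "fold": self.fold_blocks,
                "accuracy": self.fold_accuracy,
                "itr": self.fold_itr,
            }
        )


def accuracy(predictions, truths) -> float:
    """Fraction of correct predictions."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths differ in length")
    if predictions.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(predictions == truths))


def itr(P: float, Nf: int, Tw_s: float, gaze_shift_s: float = 0.0) -> float:
    """Information transfer rate in bits/min.

    Continuity conventions: ``0*log2(0) = 0`` at P in {0, 1}; a bracket
    that goes negative (below-chance accuracy) is clipped to 0.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if Nf < 2:
        raise ValueError("need at least 2 stimuli")
    if Tw_s <= 0:
        raise ValueError("selection time must be positive")
    bits = np.log2(Nf)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (Nf - 1))
    bits = max(bits, 0.0)
    return float(bits * 60.0 / (Tw_s + gaze_shift_s))


def _window_trials(
    epochs: EpochSet, window_s: float, channel_index: list[int] | None
) -> np.ndarray:
    """Cut the analysis window out of every raw trial (and subset channels)."""
    data = epochs.data if channel_index is None else epochs.data[:, channel_index, :]
    out = np.empty(
        (data.shape[0], data.shape[1], round_half_up(window_s * epochs.fs))
    )
    for t in range(data.shape[0]):
        out[t] = extract_epoch(data[t], epochs.fs, epochs.latency_s, window_s)
    return out


def leave_one_block_out(
    epochs: EpochSet,
    method: str = "htrcca",
    window_s: float = 1.0,
    Nt: int | None = None,
    Nh: int = DEFAULT_NH,
    Nb: int = DEFAULT_NB,
    n_channels: int | None = None,
    h_range: tuple[int, ...] = DEFAULT_H_RANGE,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
    seed: int = 0,
    gaze_shift_s: float = 0.0,
) -> EvalResult:
    """LOBO cross-validation of one recognizer on one epoch set.

    Parameters
    ----------
    epochs : EpochSet
        Raw trials (time axis covers latency + analysis window).
    method : str
        One of ``'cca', 'trca', 'etrca', 'htrcca', 'ehtrcca'``.
    window_s : float
        Analysis window Tw in seconds; epochs are re-windowed from raw
        trials at ``[latency, latency + Tw)``.
    Nt : int, optional
        Cap on training blocks per fold (first Nt training blocks in block
        order); default uses all B-1.
    n_channels : int, optional
        Use only the first ``n_channels`` of the channel list.
    seed : int
        Threads through the stage-1 clustering; training itself is
        deterministic.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    block_ids = np.unique(epochs.blocks)
    B = len(block_ids)
    if B < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")
    if Nt is not None and Nt > B - 1:
        raise ValueError(f"Nt={Nt} exceeds the {B - 1} available training blocks")
    chan_idx = None if n_channels is None else list(range(n_channels))
    windowed = _window_trials(epochs, window_s, chan_idx)
    n_trials, nc, ns = windowed.shape
    specs = design_subbands(epochs.fs, Nb)
    references = make_reference_bank(epochs.freqs, epochs.fs, ns, Nh)
    names = epochs.channel_names if chan_idx is None else [
        epochs.channel_names[i] for i in chan_idx
    ]

    preds: list[np.ndarray] = []
    truths: list[np.ndarray] = []
    fold_acc = np.empty(B)
    fold_itr = np.empty(B)
    for fi, held in enumerate(block_ids):
        train_blocks = [b for b in block_ids if b != held]
        if Nt is not None:
            train_blocks = train_blocks[:Nt]
        train_mask = np.isin(epochs.blocks, train_blocks)
        test_mask = epochs.blocks == held
        bank = None
        if method != "cca":
            train_set = EpochSet(
                data=windowed[train_mask],
                fs=epochs.fs,
                labels=epochs.labels[train_mask],
                blocks=epochs.blocks[train_mask],
                freqs=epochs.freqs,
                channel_names=names,
                latency_s=0.0,
            )
            bank = fit_model_bank(train_set, references, specs)
        test_idx = np.nonzero(test_mask)[0]
        p = np.empty(len(test_idx), dtype=int)
        for k, t in enumerate(test_idx):
            stack = apply_filter_bank(windowed[t], specs, epochs.fs)
            p[k] = predict_trial(
                stack,
                method,
                bank,
                references,
                specs=specs,
                fs=epochs.fs,
                h_range=h_range,
                seed=seed,
                n_restarts=n_restarts,
            )
        truth = epochs.labels[test_idx]
        preds.append(p)
        truths.append(truth)
        fold_acc[fi] = accuracy(p, truth)
        fold_itr[fi] = itr(
            fold_acc[fi], epochs.n_stimuli, window_s, gaze_shift_s
        )
    return EvalResult(
        method=method,
        fold_blocks=[int(b) for b in block_ids],
        predictions=preds,
        truths=truths,
        fold_accuracy=fold_acc,
        fold_itr=fold_itr,
        n_stimuli=epochs.n_stimuli,
        window_s=window_s,
        n_train=Nt if Nt is not None else B - 1,
        n_channels=nc,
        n_bands=Nb,
        seed=seed,
        gaze_shift_s=gaze_shift_s,
    )


def sweep(
    epochs: EpochSet,
    methods=("htrcca",),
    Nt_grid=(None,),
    Tw_grid=(1.0,),
    Nc_grid=(None,),
    Nb_grid=(DEFAULT_NB,),
    seeds=(0,),
    **kwargs,
) -> pd.DataFrame:
    """Full-factorial LOBO sweep; one output row per (cell, fold).

    Infeasible cells (e.g. Nt exceeding the available training blocks) are
    skipped with a warning and flagged by their absence.
    """
    frames = []
    for method in methods:
        for Nt in Nt_grid:
            for Tw in Tw_grid:
                for Nc in Nc_grid:
                    for Nb in Nb_grid:
                        for seed in seeds:
                            try:
                                res = leave_one_block_out(
                                    epochs,
                                    method=method,
                                    window_s=Tw,
                                    Nt=Nt,
                                    Nb=Nb,
                                    n_channels=Nc,
                                    seed=seed,
                                    **kwargs,
                                )
                            except ValueError as exc:
                                logger.warning(
                                    "sweep cell skipped (%s, Nt=%s, Tw=%s, Nc=%s, "
                                    "Nb=%s, seed=%s): %s",
                                    method, Nt, Tw, Nc, Nb, seed, exc,
                                )
                                continue
                            frames.append(res.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["method", "Nt", "Tw", "Nc", "Nb", "seed", "fold",
                     "accuracy", "itr"]
        )
    return pd.concat(frames, ignore_index=True)
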