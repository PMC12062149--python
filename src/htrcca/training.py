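"""Training phase: per-stimulus spatial filters and templates.

For every stimulus (and every filter-bank sub-band) five spatial filters are
learned from the training trials:

* ``wa, wb`` — first canonical pair between the trial-averaged template
  (tiled ``Nt`` times along the time axis) and the equally tiled sine–cosine
  reference;
* ``wc, wd`` — first canonical pair between the time-concatenated training
  trials and the tiled reference;
* ``wt`` — the task-related component analysis (TRCA) filter: the leading
  generalized eigenvector of S w = λ Q w, where S sums inter-trial
  cross-covariances and Q sums per-trial auto-covariances.  Maximizing
  wᵀSw / wᵀQw extracts the component most reproducible across trials.

Trials are mean-centered per channel before covariance computation.  The
per-stimulus template is the plain element-wise average of its training
trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .cca import cca
from .filter_bank import SubbandSpec, apply_filter_bank
from .signal_model import EpochSet, ReferenceBank

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusModel",
    "ModelBank",
    "build_template",
    "train_template_filters",
    "train_trial_filters",
    "train_trca_filter",
    "concatenate_filters",
    "fit_model_bank",
]


@dataclass
class StimulusModel:
    """Learned filters and template for one (stimulus, sub-band) pair."""

    stimulus: int
    fn: float
    band: int  # 1-based sub-band index
    wa: np.ndarray  # (Nc,)
    wb: np.ndarray  # (2*Nh,)
    wc: np.ndarray  # (Nc,)
    wd: np.ndarray  # (2*Nh,)
    wt: np.ndarray  # (Nc,)
    template: np.ndarray  # (Nc, Ns)
    n_train: int


@dataclass
class ModelBank:
    """Complete [Nf x Nb] grid of stimulus models plus training provenance."""

    models: list[list[StimulusModel]]  # indexed [stimulus][band-1]
    specs: list[SubbandSpec]
    freqs: np.ndarray
    fs: float
    Nh: int
    n_train: int
    provenance: dict = field(default_factory=dict)

    def get(self, stimulus: int, band: int) -> StimulusModel:
        """Model for 0-based stimulus index and 1-based sub-band index."""
        return self.models[stimulus][band - 1]

    @property
    def n_stimuli(self) -> int:
        return len(self.models)

    @property
    def n_bands(self) -> int:
        return len(self.specs)


def build_template(trials: np.ndarray) -> np.ndarray:
    """Element-wise average of training trials, shape (Nt, Nc, Ns) -> (Nc, Ns)."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] < 1:
        raise ValueError("need a non-empty [Nt x Nc x Ns] trial stack")
    return trials.mean(axis=0)


def _tile(M: np.ndarray, Nt: int) -> np.ndarray:
    return np.tile(M, (1, Nt))


def train_template_filters(
    template: np.ndarray, Nt: int, Yn: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """CCA filters (wa, wb) between the Nt-tiled template and tiled reference.

    Tiling leaves the canonical pair invariant (correlations are unchanged
    by repetition), so the result does not depend on ``Nt``; the tiling is
    kept to honor the stated construction.
    """
    template = np.asarray(template, dtype=float)
    if Nt < 1:
        raise ValueError("Nt must be >= 1")
    if not np.any(template - template.mean(axis=1, keepdims=True)):
        raise ValueError("degenerate (zero-variance) template")
    res = cca(_tile(template, Nt), _tile(Yn, Nt))
    return res.Wx[:, 0], res.Wy[:, 0]


def train_trial_filters(
    trials_concat: np.ndarray, Yn_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """CCA filters (wc, wd) between time-concatenated trials and tiled reference.

    ``trials_concat`` is (Nc, Ns*Nt) — trials joined along time in block
    order; ``Yn_ref`` is the reference tiled to the same length.
    """
    res = cca(trials_concat, Yn_ref)
    return res.Wx[:, 0], res.Wy[:, 0]


def train_trca_filter(trials: np.ndarray) -> np.ndarray:
    """TRCA spatial filter: leading eigenvector of the inter-trial covariance ratio.

    With per-channel-centered trials X_i, let ``Q = Σ_i X_i X_iᵀ`` (sum of
    auto-covariances) and ``S = Σ_{i≠j} X_i X_jᵀ``.  The filter maximizes
    wᵀSw / wᵀQw; returned unit-norm with the dominant entry positive.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("need [Nt x Nc x Ns] trials")
    nt, nc, _ = trials.shape
    if nt < 2:
        raise ValueError("TRCA needs at least 2 trials (inter-trial covariance)")
    centered = trials - trials.mean(axis=2, keepdims=True)
    if all(np.allclose(centered[0], centered[i]) for i in range(1, nt)):
        logger.warning(
            "all trials identical: TRCA objective is degenerate (S ∝ Q); "
            "returning the leading eigenvector anyway"
        )
    Q = np.zeros((nc, nc))
    total = np.zeros_like(centered[0])
    for i in range(nt):
        Q += centered[i] @ centered[i].T
        total += centered[i]
    # Σ_{i,j} X_i X_jᵀ = (Σ_i X_i)(Σ_j X_j)ᵀ; subtract the diagonal block Q
    S = total @ total.T - Q
    ridge = 1e-9 * np.trace(Q) / nc
    if ridge <= 0:
        raise ValueError("zero-variance trials")
    try:
        w_all, V = linalg.eigh(S, Q + ridge * np.eye(nc))
    except linalg.LinAlgError:
        logger.warning("singular TRCA denominator; increasing ridge")
        w_all, V = linalg.eigh(S, Q + 1e-4 * np.trace(Q) / nc * np.eye(nc))
    wt = V[:, np.argmax(w_all)]
    wt = wt / np.linalg.norm(wt)
    i = int(np.argmax(np.abs(wt)))
    if wt[i] < 0:
        wt = -wt
    return wt


def concatenate_filters(
    bank: "ModelBank", indices: list[int], band: int
) -> np.ndarray:
    """Stack the TRCA filters of the requested stimuli as columns, order kept.

    Returns (Nc, len(indices)); used for candidate-restricted and full
    ensemble correlation scoring.
    """
    if len(indices) == 0:
        raise ValueError("need at least one stimulus index")
    nf = bank.n_stimuli
    for i in indices:
        if not 0 <= i < nf:
            raise ValueError(f"stimulus index {i} out of range 0..{nf - 1}")
    return np.column_stack([bank.get(i, band).wt for i in indices])


def fit_model_bank(
    train: EpochSet,
    references: ReferenceBank,
    specs: list[SubbandSpec],
) -> ModelBank:
    """Train the full [Nf x Nb] grid of stimulus models.

    Every stimulus needs at least two training trials (TRCA requires
    inter-trial covariance).  Training epochs are band-filtered per
    sub-band; filters and templates are learned within each band.
    Deterministic given data and configuration.
    """
    nf = train.n_stimuli
    missing = sorted(set(range(nf)) - set(train.labels.tolist()))
    if missing:
        raise ValueError(f"stimuli missing from training data: {missing}")
    counts = np.bincount(train.labels, minlength=nf)
    if counts.min() < 2:
        low = np.nonzero(counts < 2)[0].tolist()
        raise ValueError(f"stimuli with fewer than 2 training trials: {low}")

    # band-filter every training trial once
    banded = np.empty((len(specs),) + train.data.shape)
    for t in range(train.n_trials):
        banded[:, t] = apply_filter_bank(train.data[t], specs, train.fs).data

    models: list[list[StimulusModel]] = []
    for n in range(nf):
        # block order for deterministic concatenation
        idx = np.nonzero(train.labels == n)[0]
        idx = idx[np.argsort(train.blocks[idx], kind="stable")]
        Yn = references[n]
        per_band: list[StimulusModel] = []
        for bi, spec in enumerate(specs):
            trials = banded[bi, idx]  # (Nt, Nc, Ns)
            nt = trials.shape[0]
            template = build_template(trials)
            wa, wb = train_template_filters(template, nt, Yn)
            concat = np.concatenate(list(trials), axis=1)
            wc, wd = train_trial_filters(concat, _tile(Yn, nt))
            wt = train_trca_filter(trials)
            per_band.append(
                StimulusModel(
                    stimulus=n,
                    fn=float(train.freqs[n]),
                    band=spec.b,
                    wa=wa,
                    wb=wb,
                    wc=wc,
                    wd=wd,
                    wt=wt,
                    template=template,
                    n_train=nt,
                )
            )
        models.append(per_band)
    return ModelBank(
        models=models,
        specs=list(specs),
        freqs=train.freqs.copy(),
        fs=train.fs,
        Nh=references.Nh,
        n_train=int(counts.min()),
    )
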