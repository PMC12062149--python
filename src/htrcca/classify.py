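"""Test-phase recognizers: H-TRCCA, its ensemble variant, and baselines.

The hybrid recognizer scores a test epoch in two stages.  Stage 1 computes,
for every stimulus and every filter-bank sub-band, five correlation
features:

1. the first canonical correlation between the banded epoch and the
   stimulus's sine–cosine reference (calibration-free CCA feature);
2. Pearson correlation of the wa-projected epoch and wa-projected template;
3. Pearson correlation of the wa-projected epoch and wb-projected reference;
4. Pearson correlation of the wc-projected epoch and wd-projected reference;
5. Pearson correlation of the wc-projected epoch and wc-projected template.

Each component is fused across sub-bands as a weighted sum of squares,
giving a non-negative (Nf, 5) feature matrix; clustering those rows
shortlists candidate stimuli.  Stage 2 sums each candidate's five features
(T), adds a TRCA ensemble-correlation term computed with the candidates'
concatenated spatial filters (D), and picks the candidate maximizing
C = T + D.  Ties break to the lowest stimulus index throughout.

Baselines share the same filter-bank fusion: plain CCA (feature 1 only),
TRCA (per-stimulus filter correlation), and eTRCA (all-stimulus ensemble
correlation).  eH-TRCCA replaces the candidate-restricted ensemble in stage
2 with the full-bank ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cca import (
    center_whiten,
    matrix_correlation,
    max_canonical_correlation,
    max_corr_precomputed,
    pearson,
)
from .clustering import (
    DEFAULT_GMM_RESTARTS,
    DEFAULT_H_RANGE,
    CandidateSet,
    FeatureMatrix,
    cluster_features,
    pick_candidates,
    select_cluster_count,
)
from .filter_bank import SubbandStack, apply_filter_bank, combine_subbands
from .signal_model import ReferenceBank
from .training import ModelBank, concatenate_filters

logger = logging.getLogger(__name__)

__all__ = [
    "Decision",
    "feature_vector",
    "stage1",
    "stage2",
    "classify",
    "cca_scores",
    "cca_classify",
    "trca_scores",
    "trca_classify",
    "ensemble_correlation",
    "etrca_scores",
    "etrca_classify",
    "ehtrcca_classify",
    "METHODS",
]


@dataclass
class Decision:
    """Outcome of a two-stage classification of one test epoch."""

    predicted: int
    C: np.ndarray  # per-candidate combined scores
    T: np.ndarray  # per-candidate summed features
    D: np.ndarray  # per-candidate ensemble-correlation scores
    candidates: CandidateSet
    features: FeatureMatrix


def _banded(X_test: np.ndarray | SubbandStack, bank: ModelBank) -> SubbandStack:
    if isinstance(X_test, SubbandStack):
        return X_test
    return apply_filter_bank(np.asarray(X_test, dtype=float), bank.specs, bank.fs)


def _reference_whitening(references: ReferenceBank):
    """Centered/whitened copies of every reference, cached on the bank."""
    cache = getattr(references, "_whiten_cache", None)
    if cache is None or len(cache) != references.n_stimuli:
        cache = [center_whiten(references[n]) for n in range(references.n_stimuli)]
        references._whiten_cache = cache
    return cache


def _all_feature_vectors(
    stack: SubbandStack, bank: ModelBank, references: ReferenceBank
) -> np.ndarray:
    """Fused (Nf, 5) feature matrix for every stimulus hypothesis at once.

    Same mathematics as :func:`feature_vector`, but the per-band whitening
    of the epoch and the whitening of each reference are computed once and
    shared across the Nf x Nb grid.
    """
    nf = bank.n_stimuli
    refs = _reference_whitening(references)
    raw = np.empty((nf, 5, stack.n_bands))
    for bi in range(stack.n_bands):
        Xb = stack[bi]
        Xc, Kx = center_whiten(Xb)
        for n in range(nf):
            Yc, Ky = refs[n]
            m = bank.get(n, bi + 1)
            raw[n, 0, bi] = max_corr_precomputed(Xc, Kx, Yc, Ky)
            pa = m.wa @ Xb
            pc = m.wc @ Xb
            Yn = references[n]
            raw[n, 1, bi] = pearson(pa, m.wa @ m.template)
            raw[n, 2, bi] = pearson(pa, m.wb @ Yn)
            raw[n, 3, bi] = pearson(pc, m.wd @ Yn)
            raw[n, 4, bi] = pearson(pc, m.wc @ m.template)
    return np.stack(
        [
            [combine_subbands(raw[n, s]) for s in range(5)]
            for n in range(nf)
        ]
    )


def feature_vector(
    X_test: np.ndarray | SubbandStack,
    stimulus: int,
    bank: ModelBank,
    references: ReferenceBank,
) -> np.ndarray:
    """Five sub-band-fused correlation features for one stimulus hypothesis.

    Accepts a raw (Nc, Ns) epoch or a pre-banded :class:`SubbandStack`.
    Returns a non-negative length-5 vector.
    """
    stack = _banded(X_test, bank)
    Yn = references[stimulus]
    raw = np.empty((5, stack.n_bands))
    for bi in range(stack.n_bands):
        Xb = stack[bi]
        m = bank.get(stimulus, bi + 1)
        raw[0, bi] = max_canonical_correlation(Xb, Yn)
        pa = m.wa @ Xb
        pc = m.wc @ Xb
        raw[1, bi] = pearson(pa, m.wa @ m.template)
        raw[2, bi] = pearson(pa, m.wb @ Yn)
        raw[3, bi] = pearson(pc, m.wd @ Yn)
        raw[4, bi] = pearson(pc, m.wc @ m.template)
    return np.array([combine_subbands(raw[s]) for s in range(5)])


def stage1(
    X_test: np.ndarray | SubbandStack,
    bank: ModelBank,
    references: ReferenceBank,
    h_range: tuple[int, ...] = DEFAULT_H_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
) -> tuple[FeatureMatrix, CandidateSet]:
    """Compute all-stimulus features and shortlist candidates by clustering."""
    stack = _banded(X_test, bank)
    nf = bank.n_stimuli
    feats = FeatureMatrix(values=_all_feature_vectors(stack, bank, references))
    values = feats.values
    if nf <= 2:
        logger.warning(
            "only %d stimuli: below the clustering minimum, all are candidates", nf
        )
        cands = CandidateSet(
            indices=np.arange(nf),
            h_selected=1,
            cluster_means=np.array([values.mean()]),
        )
        return feats, cands
    h = select_cluster_count(values, h_range=h_range, seed=seed, n_restarts=n_restarts)
    labels = cluster_features(values, h, seed=seed)
    return feats, pick_candidates(values, labels)


def stage2(
    X_test: np.ndarray | SubbandStack,
    candidates: CandidateSet,
    features: FeatureMatrix,
    bank: ModelBank,
    ensemble: np.ndarray | None = None,
) -> Decision:
    """Score candidates by C = T + D and return the argmax decision.

    ``T_k`` sums candidate k's five fused features.  ``D_k`` is the fused
    ensemble correlation computed with the candidates' concatenated TRCA
    filters per sub-band — or with ``ensemble`` (a (Nf,) index array of
    stimuli to pool, used by the full-bank eH-TRCCA variant).  A singleton
    candidate set short-circuits: a one-column ensemble adds the same
    information to its only competitor, so D is skipped.
    """
    idx = candidates.indices
    m = len(idx)
    T = features.values[idx].sum(axis=1)
    if m == 1:
        return Decision(
            predicted=int(idx[0]),
            C=T.copy(),
            T=T,
            D=np.zeros(1),
            candidates=candidates,
            features=features,
        )
    stack = _banded(X_test, bank)
    pool = list(idx) if ensemble is None else list(ensemble)
    raw_d = np.empty((m, stack.n_bands))
    for bi in range(stack.n_bands):
        W = concatenate_filters(bank, pool, bi + 1)
        proj = stack[bi].T @ W
        for k, n in enumerate(idx):
            tmpl = bank.get(n, bi + 1).template
            raw_d[k, bi] = matrix_correlation(proj, tmpl.T @ W)
    D = np.array([combine_subbands(raw_d[k]) for k in range(m)])
    C = T + D
    win = int(np.argmax(C))  # first max -> lowest stimulus index
    return Decision(
        predicted=int(idx[win]), C=C, T=T, D=D, candidates=candidates, features=features
    )


def classify(
    X_test: np.ndarray,
    bank: ModelBank,
    references: ReferenceBank,
    h_range: tuple[int, ...] = DEFAULT_H_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
) -> Decision:
    """Full two-stage H-TRCCA recognition of one test epoch."""
    stack = _banded(X_test, bank)
    feats, cands = stage1(
        stack, bank, references, h_range=h_range, seed=seed, n_restarts=n_restarts
    )
    return stage2(stack, cands, feats, bank)


def ehtrcca_classify(
    X_test: np.ndarray,
    bank: ModelBank,
    references: ReferenceBank,
    h_range: tuple[int, ...] = DEFAULT_H_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
) -> Decision:
    """Ensemble H-TRCCA: stage-2 D uses the full-bank ensemble filter.

    TRCA filters of *all* stimuli are pooled into one wide spatial filter
    (filters for the same band are assumed similar across stimuli); scoring
    is still restricted to the stage-1 candidates.
    """
    stack = _banded(X_test, bank)
    feats, cands = stage1(
        stack, bank, references, h_range=h_range, seed=seed, n_restarts=n_restarts
    )
    return stage2(
        stack, cands, feats, bank, ensemble=np.arange(bank.n_stimuli)
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def cca_scores(
    X_test: np.ndarray | SubbandStack,
    references: ReferenceBank,
    specs=None,
    fs: float | None = None,
) -> np.ndarray:
    """Calibration-free CCA scores: fused first canonical correlations.

    Needs no training; ``specs``/``fs`` describe the filter bank when
    ``X_test`` is a raw epoch rather than a pre-banded stack.
    """
    if isinstance(X_test, SubbandStack):
        stack = X_test
    else:
        if specs is None or fs is None:
            raise ValueError("raw-epoch CCA scoring needs sub-band specs and fs")
        stack = apply_filter_bank(np.asarray(X_test, dtype=float), specs, fs)
    nf = references.n_stimuli
    refs = _reference_whitening(references)
    raw = np.empty((nf, stack.n_bands))
    for bi in range(stack.n_bands):
        Xc, Kx = center_whiten(stack[bi])
        for n in range(nf):
            Yc, Ky = refs[n]
            raw[n, bi] = max_corr_precomputed(Xc, Kx, Yc, Ky)
    return np.array([combine_subbands(raw[n]) for n in range(nf)])


def cca_classify(
    X_test: np.ndarray | SubbandStack,
    references: ReferenceBank,
    specs=None,
    fs: float | None = None,
) -> int:
    return int(np.argmax(cca_scores(X_test, references, specs, fs)))


def trca_scores(X_test: np.ndarray | SubbandStack, bank: ModelBank) -> np.ndarray:
    """TRCA scores: fused correlations of wt-projected epoch vs template."""
    stack = _banded(X_test, bank)
    out = np.empty(bank.n_stimuli)
    for n in range(bank.n_stimuli):
        raw = np.empty(stack.n_bands)
        for bi in range(stack.n_bands):
            m = bank.get(n, bi + 1)
            raw[bi] = pearson(m.wt @ stack[bi], m.wt @ m.template)
        out[n] = combine_subbands(raw)
    return out


def trca_classify(X_test: np.ndarray, bank: ModelBank) -> int:
    return int(np.argmax(trca_scores(X_test, bank)))


def ensemble_correlation(
    X_test: np.ndarray | SubbandStack, stimulus: int, bank: ModelBank
) -> float:
    """Fused full-bank ensemble correlation score for one stimulus."""
    stack = _banded(X_test, bank)
    all_idx = list(range(bank.n_stimuli))
    raw = np.empty(stack.n_bands)
    for bi in range(stack.n_bands):
        W = concatenate_filters(bank, all_idx, bi + 1)
        tmpl = bank.get(stimulus, bi + 1).template
        raw[bi] = matrix_correlation(stack[bi].T @ W, tmpl.T @ W)
    return combine_subbands(raw)


def etrca_scores(X_test: np.ndarray | SubbandStack, bank: ModelBank) -> np.ndarray:
    """eTRCA scores: full-ensemble correlation per stimulus."""
    stack = _banded(X_test, bank)
    all_idx = list(range(bank.n_stimuli))
    raw = np.empty((bank.n_stimuli, stack.n_bands))
    for bi in range(stack.n_bands):
        W = concatenate_filters(bank, all_idx, bi + 1)
        proj = stack[bi].T @ W
        for n in range(bank.n_stimuli):
            tmpl = bank.get(n, bi + 1).template
            raw[n, bi] = matrix_correlation(proj, tmpl.T @ W)
    return np.array([combine_subbands(raw[n]) for n in range(bank.n_stimuli)])


def etrca_classify(X_test: np.ndarray, bank: ModelBank) -> int:
    return int(np.argmax(etrca_scores(X_test, bank)))


def predict_trial(
    X_test: np.ndarray | SubbandStack,
    method: str,
    bank: ModelBank | None,
    references: ReferenceBank,
    specs=None,
    fs: float | None = None,
    h_range: tuple[int, ...] = DEFAULT_H_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
) -> int:
    """Dispatch one-epoch recognition by method name.

    ``method`` is one of 'cca', 'trca', 'etrca', 'htrcca', 'ehtrcca'; all
    but 'cca' require a fitted :class:`ModelBank` (which also carries the
    sub-band specs); plain 'cca' can run from ``specs``/``fs`` alone.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    if method != "cca" and bank is None:
        raise ValueError(f"method {method!r} requires a trained model bank")
    if method == "cca":
        if bank is not None and specs is None:
            specs, fs = bank.specs, bank.fs
        return cca_classify(X_test, references, specs, fs)
    if method == "trca":
        return trca_classify(X_test, bank)
    if method == "etrca":
        return etrca_classify(X_test, bank)
    if method == "htrcca":
        return classify(
            X_test, bank, references, h_range=h_range, seed=seed, n_restarts=n_restarts
        ).predicted
    return ehtrcca_classify(
        X_test, bank, references, h_range=h_range, seed=seed, n_restarts=n_restarts
    ).predicted


METHODS = ("cca", "trca", "etrca", "htrcca", "ehtrcca")
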