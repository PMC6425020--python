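"""Time-resolved pairwise decoding: RDMs, image decoding, generalization.

For every time point and every unordered pair of conditions, trials are
randomly sub-averaged into pseudo-trials (five splits by default), a linear
max-margin classifier is trained with leave-one-split-out cross-validation,
and the cross-validated accuracy becomes the pair's dissimilarity.  Fresh
random sub-averagings are drawn ``n_repetitions`` times and accuracies
averaged, yielding one symmetric condition x condition RDM (undefined
diagonal) per time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from . import _svm
from .core import ComponentEpochs, ConditionTable, RDMSeries, square_from_lower_triangle

__all__ = [
    "DecodingConfig",
    "subaverage_trials",
    "pairwise_decode_timepoint",
    "build_rdm_series",
    "image_decoding_timecourse",
    "temporal_generalization",
    "cross_category_decode",
]

# Gram matrices are built in time chunks to bound memory at full design scale.
_TIME_CHUNK_BYTES = 128 * 1024**2


@dataclass
class DecodingConfig:
    """Sub-averaging and cross-validation settings for pairwise decoding.

    Each of the ``n_splits_subaverage`` splits serves once as the held-out
    fold, so ``n_folds`` must equal the split count.  ``C`` is the fixed
    regularization of the linear classifier, applied to unscaled component
    scores.
    """

    n_splits_subaverage: int = 5
    n_folds: int = 5
    n_repetitions: int = 100
    C: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_folds != self.n_splits_subaverage:
            raise ValueError("n_folds must equal n_splits_subaverage (one split per fold)")
        if self.n_splits_subaverage < 2:
            raise ValueError("need at least two sub-average splits")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")


def subaverage_trials(trials: np.ndarray, n_splits: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly partition trials into near-equal splits and average each.

    ``trials`` is ``[k, ...]`` with ``k >= n_splits``; returns
    ``[n_splits, ...]``.  Group sizes differ by at most one; when they are
    equal the grand mean of the output equals the grand mean of the input.
    """
    trials = np.asarray(trials)
    k = trials.shape[0]
    if k < n_splits:
        raise ValueError(f"cannot form {n_splits} splits from {k} trials (under-sampled)")
    perm = rng.permutation(k)
    out = np.empty((n_splits,) + trials.shape[1:], dtype=float)
    for s in range(n_splits):
        out[s] = trials[perm[s::n_splits]].mean(axis=0)
    return out


def pairwise_decode_timepoint(
    pseudo_a: np.ndarray, pseudo_b: np.ndarray, config: DecodingConfig = None
) -> float:
    """Leave-one-split-out CV accuracy for one pair of pseudo-trial sets.

    ``pseudo_a`` and ``pseudo_b`` are ``[n_splits, n_features]`` sub-averaged
    pseudo-trials (sub-averaging, and its repetition, happen upstream in
    :func:`build_rdm_series`).  Per fold, the classifier trains on the other
    ``n_splits - 1`` pseudo-trials of each class and classifies the held-out
    pair; the returned accuracy is the fraction of correct held-out
    classifications.  Degenerate all-constant features score chance (0.5)
    with a warning.
    """
    config = config or DecodingConfig()
    a = np.atleast_2d(np.asarray(pseudo_a, dtype=float))
    b = np.atleast_2d(np.asarray(pseudo_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("pseudo-trial sets must have matching shapes")
    n_splits = a.shape[0]
    if n_splits < 2:
        raise ValueError("need at least two splits for cross-validation")
    both = np.concatenate([a, b], axis=0)
    if np.ptp(both, axis=0).max(initial=0.0) == 0.0:
        warnings.warn("all-constant features; returning chance accuracy 0.5", stacklevel=2)
        return 0.5
    correct = 0
    for fold in range(n_splits):
        keep = np.arange(n_splits) != fold
        X = np.concatenate([a[keep], b[keep]], axis=0)
        y = np.concatenate([np.ones(n_splits - 1), -np.ones(n_splits - 1)])
        alpha, bias = _svm.solve_linear_svm(X, y, C=config.C)
        coef = alpha * y
        dec_a = float(coef @ (X @ a[fold]) + bias)
        dec_b = float(coef @ (X @ b[fold]) + bias)
        correct += int(dec_a > 0) + int(dec_b <= 0)
    return correct / (2.0 * n_splits)


def _trials_by_condition(
    component_epochs: ComponentEpochs, conditions: ConditionTable, n_splits: int
) -> list:
    groups = []
    short = []
    for cid in conditions.condition_ids:
        idx = np.where((component_epochs.condition_id == cid) & component_epochs.valid)[0]
        if idx.size < n_splits:
            short.append(int(cid))
        groups.append(idx)
    if short:
        raise ValueError(
            f"conditions with fewer valid trials than sub-average splits: {short}"
        )
    return groups


def _pseudotrials(
    features: np.ndarray, groups: list, n_splits: int, rng: np.random.Generator
) -> np.ndarray:
    """Sub-averaged pseudo-trials ``[T, n_conditions * n_splits, d]``.

    ``features`` is ``[n_trials, d, T]``; one fresh random partition per
    condition.
    """
    n_cond = len(groups)
    d = features.shape[1]
    T = features.shape[2]
    out = np.empty((T, n_cond * n_splits, d))
    for c, idx in enumerate(groups):
        perm = rng.permutation(idx.size)
        for s in range(n_splits):
            sel = idx[perm[s::n_splits]]
            # [len, d, T] -> mean over trials -> [T, d]
            out[:, c * n_splits + s, :] = features[sel].mean(axis=0).T
    return out


def _analysis_time_mask(times: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones(times.size, dtype=bool)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"analysis window {window} contains no samples")
    return mask


def build_rdm_series(
    component_epochs: ComponentEpochs,
    conditions: ConditionTable,
    config: DecodingConfig = None,
    window=None,
) -> RDMSeries:
    """Cross-validated pairwise decoding RDM at every time point.

    All ``n * (n - 1) / 2`` unordered condition pairs are decoded with
    leave-one-split-out CV, averaged over ``config.n_repetitions`` fresh
    sub-averagings, and stored symmetrically with an undefined diagonal.
    ``window`` optionally restricts the analyzed time axis (in ms).
    """
    config = config or DecodingConfig()
    S = config.n_splits_subaverage
    groups = _trials_by_condition(component_epochs, conditions, S)
    mask = _analysis_time_mask(component_epochs.times, window)
    times = component_epochs.times[mask]
    features = component_epochs.data[:, :, mask]
    n_cond = len(groups)
    tri_i, tri_j = np.tril_indices(n_cond, k=-1)
    pairs_a = tri_i.astype(np.int64)
    pairs_b = tri_j.astype(np.int64)

    rng = np.random.default_rng(config.seed)
    T = times.size
    acc_sum = np.zeros((T, pairs_a.size))
    M = n_cond * S
    chunk = max(1, _TIME_CHUNK_BYTES // (M * M * 8))
    for _ in range(config.n_repetitions):
        P = _pseudotrials(features, groups, S, rng)
        for t0 in range(0, T, chunk):
            t1 = min(T, t0 + chunk)
            G = np.matmul(P[t0:t1], P[t0:t1].transpose(0, 2, 1))
            acc_sum[t0:t1] += _svm.decode_pairs_kernel(
                G, pairs_a, pairs_b, S, config.C, _svm._DEFAULT_TOL, _svm._MAX_SWEEPS
            )
    acc = acc_sum / config.n_repetitions
    values = square_from_lower_triangle(acc, n_cond)
    return RDMSeries(values=values, times=times, condition_ids=conditions.condition_ids.copy())


def image_decoding_timecourse(rdms: RDMSeries) -> np.ndarray:
    """Mean of the strictly-lower-triangle accuracies per time point."""
    return rdms.mean_dissimilarity()


def temporal_generalization(
    component_epochs: ComponentEpochs,
    conditions: ConditionTable,
    config: DecodingConfig = None,
    train_times: np.ndarray = None,
    test_times: np.ndarray = None,
    window=None,
    train_stride: int = 10,
):
    """Train at one time point, test the held-out split at all others.

    Returns ``(matrix, train_times, test_times)`` where ``matrix`` is
    ``[n_train, n_test]`` mean pairwise accuracy.  By default training times
    subsample every ``train_stride``-th analyzed time point for tractability;
    the diagonal equals the standard decoding time course up to sub-averaging
    randomness.
    """
    config = config or DecodingConfig()
    S = config.n_splits_subaverage
    groups = _trials_by_condition(component_epochs, conditions, S)
    mask = _analysis_time_mask(component_epochs.times, window)
    times = component_epochs.times[mask]
    features = component_epochs.data[:, :, mask]
    if test_times is None:
        test_times = times
    if train_times is None:
        train_times = times[::train_stride]
    train_idx = np.asarray([int(np.argmin(np.abs(times - t))) for t in np.atleast_1d(train_times)])
    test_idx = np.asarray([int(np.argmin(np.abs(times - t))) for t in np.atleast_1d(test_times)])

    n_cond = len(groups)
    tri_i, tri_j = np.tril_indices(n_cond, k=-1)
    pairs_a = tri_i.astype(np.int64)
    pairs_b = tri_j.astype(np.int64)
    rng = np.random.default_rng(config.seed)
    out = np.zeros((train_idx.size, test_idx.size))
    for _ in range(config.n_repetitions):
        P = _pseudotrials(features, groups, S, rng)
        P_test = np.ascontiguousarray(P[test_idx])
        for r, ti in enumerate(train_idx):
            out[r] += _svm.temporal_generalization_kernel(
                np.ascontiguousarray(P[ti]),
                P_test,
                pairs_a,
                pairs_b,
                S,
                config.C,
                _svm._DEFAULT_TOL,
                _svm._MAX_SWEEPS,
            )
    out /= config.n_repetitions
    return out, times[train_idx], times[test_idx]


def _stratified_level_folds(
    level_of: dict, categories: np.ndarray, n_groups: int, rng: np.random.Generator
) -> list:
    """Partition grouping levels into folds, each containing every category."""
    folds = [[] for _ in range(n_groups)]
    for cat in np.unique(categories):
        levels = [lv for lv, c in level_of.items() if c == cat]
        order = rng.permutation(len(levels))
        for pos, o in enumerate(order):
            folds[pos % n_groups].append(levels[o])
    return folds


def cross_category_decode(
    component_epochs: ComponentEpochs,
    conditions: ConditionTable,
    category_factor: str,
    grouping_factor: str,
    config: DecodingConfig = None,
    n_groups: int = 4,
    window=None,
    time_stride: int = 1,
):
    """Decode a category across held-out levels of a nested grouping factor.

    E.g. train a gender classifier on a subset of identities and test it on
    pseudo-trials of the left-out identities, so accuracy above chance (0.5)
    reflects a category code that generalizes across the grouping factor.
    Folds are stratified so every held-out set contains both category levels.
    Returns ``(accuracy, times)``.
    """
    config = config or DecodingConfig()
    S = config.n_splits_subaverage
    cats = conditions.factor(category_factor)
    if np.unique(cats).size != 2:
        raise ValueError(f"category factor {category_factor!r} must have exactly 2 levels")
    groups_f = conditions.factor(grouping_factor)
    level_of = {}
    for lv, cat in zip(groups_f, cats):
        if lv in level_of and level_of[lv] != cat:
            raise ValueError(
                f"grouping factor {grouping_factor!r} is not nested within {category_factor!r}"
            )
        level_of[lv] = cat
    per_cat = {c: sum(1 for v in level_of.values() if v == c) for c in np.unique(cats)}
    n_groups = min(n_groups, min(per_cat.values()))
    if n_groups < 2:
        raise ValueError("need at least two grouping levels per category to cross-validate")

    groups = _trials_by_condition(component_epochs, conditions, S)
    mask = _analysis_time_mask(component_epochs.times, window)
    times = component_epochs.times[mask][::time_stride]
    t_sel = np.where(mask)[0][::time_stride]
    features = component_epochs.data
    cat_levels = np.unique(cats)
    y_cond = np.where(cats == cat_levels[0], 1.0, -1.0)

    rng = np.random.default_rng(config.seed)
    acc = np.zeros(times.size)
    n_eval = 0
    for _ in range(config.n_repetitions):
        P = _pseudotrials(features[:, :, t_sel], groups, S, rng)  # [T, C*S, d]
        folds = _stratified_level_folds(level_of, cats, n_groups, rng)
        for held_out in folds:
            test_mask = np.isin(groups_f, held_out)
            train_mask = ~test_mask
            rows_train = np.concatenate(
                [np.arange(c * S, (c + 1) * S) for c in np.where(train_mask)[0]]
            )
            rows_test = np.concatenate(
                [np.arange(c * S, (c + 1) * S) for c in np.where(test_mask)[0]]
            )
            y_train = np.repeat(y_cond[train_mask], S)
            y_test = np.repeat(y_cond[test_mask], S)
            if np.unique(y_test).size < 2 or np.unique(y_train).size < 2:
                raise ValueError("fold with a single-class train or test set")
            for ti in range(times.size):
                clf = SVC(kernel="linear", C=config.C)
                clf.fit(P[ti, rows_train], y_train)
                acc[ti] += float(np.mean(clf.predict(P[ti, rows_test]) == y_test))
        n_eval += len(folds)
    return acc / n_eval, times
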