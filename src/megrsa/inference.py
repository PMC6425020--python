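"""Group-level nonparametric inference over time.

Cluster-based sign-permutation testing: each permutation flips whole subject
time courses (centered by the chance level) by +/-1; per-timepoint
cluster-inducing thresholds are the 95th percentile of the permutation
distribution of group means ("higher" interpolation so small-sample
enumeration is exact); the cluster-length criterion is the smallest run
length whose permutation tail probability is at or below the corrected
alpha, which keeps family-wise error controlled despite the discreteness of
run lengths.  The identity sign assignment is always included in the
permutation set, guaranteeing p > 0.  When all sign patterns fit in the
permutation budget the test enumerates them exhaustively and is exact.

Onset and peak latencies are estimated by bootstrapping subjects with
replacement, re-running the cluster test per resample; onset is the earliest
cluster-corrected significant time point after stimulus onset, peak the
maximum of the group statistic inside a fixed early search window
(80-180 ms by default).  Latency differences use paired bootstrap draws and
a two-sided sign-counting p-value floored at 2 / n_bootstrap; families of
latency comparisons are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._utils import contiguous_runs, max_run_length
from .core import ClusterResult, GroupTimecourse, LatencyEstimate

__all__ = [
    "cluster_sign_permutation",
    "bootstrap_latencies",
    "bootstrap_latencies_paired",
    "latency_difference_test",
    "fdr_correct",
]


def _sign_matrix(n_subjects: int, n_permutations: int, rng: np.random.Generator):
    """Sign-flip matrix [n_perm, n_subjects]; exhaustive when it fits.

    The identity assignment (all +1) is always the first row.
    """
    if 2**n_subjects <= n_permutations:
        n = 2**n_subjects
        bits = (np.arange(n)[:, None] >> np.arange(n_subjects)[None, :]) & 1
        signs = 1.0 - 2.0 * bits
        # put the all-ones pattern first (it is the row of all zero bits)
        return signs, True
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects))
    signs[0] = 1.0
    return signs, False


def _critical_run_length(max_runs: np.ndarray, alpha: float) -> int:
    """Smallest L with P(max run >= L) <= alpha under the permutation null."""
    n = max_runs.size
    for L in range(1, int(max_runs.max()) + 2):
        if np.count_nonzero(max_runs >= L) <= alpha * n:
            return L
    return int(max_runs.max()) + 1


def cluster_sign_permutation(
    tc: GroupTimecourse,
    n_permutations: int = 1000,
    alpha_cluster: float = 0.05,
    alpha_corrected: float = 0.05,
    seed: int = 0,
    tail: int = 1,
) -> ClusterResult:
    """Cluster-corrected one-sided sign-permutation test of a group time course.

    ``tail=1`` tests for positive deviations from the chance level (the
    default, matching decoding-above-chance and positive-correlation
    hypotheses); ``tail=-1`` for negative; ``tail=0`` two-sided (thresholds
    on the absolute group mean).
    """
    X = tc.data - tc.chance_level
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the group time course")
    n_subjects, n_tp = X.shape
    if n_subjects < 2:
        raise ValueError("need at least two subjects for sign permutation")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is low; thresholds will be coarse",
            stacklevel=2,
        )
    if tail == -1:
        X = -X
    rng = np.random.default_rng(seed)
    signs, exact = _sign_matrix(n_subjects, n_permutations, rng)
    perm_means = signs @ X / n_subjects          # [n_perm, n_tp]
    if tail == 0:
        perm_means = np.abs(perm_means)
    q = 100.0 * (1.0 - alpha_cluster)
    thresh = np.percentile(perm_means, q, axis=0, method="higher")
    supra = perm_means > thresh[None, :]
    max_runs = max_run_length(supra)
    L_crit = _critical_run_length(max_runs, alpha_corrected)

    observed_supra = supra[0]                    # identity permutation row
    significant = np.zeros(n_tp, dtype=bool)
    clusters = []
    n_perm_eff = perm_means.shape[0]
    for start, stop in contiguous_runs(observed_supra):
        length = stop - start + 1
        p_val = float(np.count_nonzero(max_runs >= length)) / n_perm_eff
        if length >= L_crit:
            significant[start : stop + 1] = True
            clusters.append(
                dict(
                    start_ms=float(tc.times[start]),
                    end_ms=float(tc.times[stop]),
                    length=int(length),
                    p_value=p_val,
                )
            )
    return ClusterResult(
        significant=significant,
        clusters=clusters,
        pointwise_threshold=thresh,
        suprathreshold=observed_supra,
        cluster_length_threshold=L_crit,
        n_permutations=n_perm_eff,
        times=tc.times.copy(),
        seed=None if exact else seed,
    )


def _onset_from_cluster(result: ClusterResult) -> float:
    return result.onset_ms()


def _peak_latency(mean_tc: np.ndarray, times: np.ndarray, window) -> float:
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"peak window {window} outside the analyzed times")
    sub = mean_tc[mask]
    return float(times[mask][int(np.argmax(sub))])


def bootstrap_latencies_paired(
    tcs: dict,
    n_bootstrap: int = 1000,
    n_permutations: int = 1000,
    alpha_cluster: float = 0.05,
    alpha_corrected: float = 0.05,
    peak_window=(80.0, 180.0),
    seed: int = 0,
    tail: int = 1,
) -> dict:
    """Bootstrap onset/peak latencies for several time courses with paired draws.

    Every bootstrap draw resamples one set of subjects with replacement and
    evaluates all time courses on it, so the per-draw latency samples are
    paired across conditions and can feed
    :func:`latency_difference_test` directly.  Cluster-permutation
    thresholds are recomputed inside every resample.  Draws in which a time
    course has no significant post-onset time point are excluded from its
    onset distribution and counted; if more than half the draws lack an
    onset the onset CI is flagged unreportable.
    """
    items = list(tcs.items())
    n_subjects = items[0][1].n_subjects
    times = items[0][1].times
    for _, tc in items:
        if tc.n_subjects != n_subjects or not np.allclose(tc.times, times):
            raise ValueError("all time courses must share subjects and time axis")
    if not (times > 0).any():
        raise ValueError("no post-stimulus time points")
    rng = np.random.default_rng(seed)

    onset_samples = {name: np.full(n_bootstrap, np.nan) for name, _ in items}
    peak_samples = {name: np.full(n_bootstrap, np.nan) for name, _ in items}
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_subjects, size=n_subjects)
        perm_seed = int(rng.integers(0, 2**31 - 1))
        for name, tc in items:
            sub = GroupTimecourse(tc.data[idx], times, chance_level=tc.chance_level)
            res = cluster_sign_permutation(
                sub,
                n_permutations=n_permutations,
                alpha_cluster=alpha_cluster,
                alpha_corrected=alpha_corrected,
                seed=perm_seed,
                tail=tail,
            )
            onset_samples[name][b] = res.onset_ms()
            peak_samples[name][b] = _peak_latency(sub.mean(), times, peak_window)

    out = {}
    for name, tc in items:
        observed = cluster_sign_permutation(
            tc,
            n_permutations=n_permutations,
            alpha_cluster=alpha_cluster,
            alpha_corrected=alpha_corrected,
            seed=int(np.random.default_rng(seed).integers(0, 2**31 - 1)),
            tail=tail,
        )
        onset_pt = observed.onset_ms()
        peak_pt = _peak_latency(tc.mean(), times, peak_window)
        ons = onset_samples[name]
        valid = ons[np.isfinite(ons)]
        n_missing = n_bootstrap - valid.size
        reportable = n_missing <= n_bootstrap // 2
        if reportable and valid.size:
            ci = (
                float(np.percentile(valid, 2.5)),
                float(np.percentile(valid, 97.5)),
            )
        else:
            ci = (np.nan, np.nan)
        pk = peak_samples[name]
        peak_ci = (float(np.percentile(pk, 2.5)), float(np.percentile(pk, 97.5)))
        out[name] = LatencyEstimate(
            onset_ms=onset_pt,
            onset_ci=ci,
            peak_ms=peak_pt,
            peak_ci=peak_ci,
            peak_window=tuple(peak_window),
            n_bootstrap=n_bootstrap,
            n_missing_onset=n_missing,
            onset_samples=ons,
            peak_samples=pk,
            onset_reportable=reportable,
        )
    return out


def bootstrap_latencies(
    tc: GroupTimecourse,
    n_bootstrap: int = 1000,
    n_permutations: int = 1000,
    alpha_cluster: float = 0.05,
    alpha_corrected: float = 0.05,
    peak_window=(80.0, 180.0),
    seed: int = 0,
    tail: int = 1,
) -> LatencyEstimate:
    """Bootstrap onset/peak latency CIs for a single group time course."""
    return bootstrap_latencies_paired(
        {"tc": tc},
        n_bootstrap=n_bootstrap,
        n_permutations=n_permutations,
        alpha_cluster=alpha_cluster,
        alpha_corrected=alpha_corrected,
        peak_window=peak_window,
        seed=seed,
        tail=tail,
    )["tc"]


def latency_difference_test(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Two-sided bootstrap p-value for a latency difference.

    ``samples_a`` and ``samples_b`` must come from paired bootstrap draws
    (same resampled subject sets per draw).  The p-value counts bootstrap
    differences on either side of zero, doubles the smaller tail, and is
    floored at ``2 / n`` (draws where either latency is undefined are
    dropped first).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired bootstrap samples must have equal counts")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    n = d.size
    if n == 0:
        raise ValueError("no valid paired bootstrap differences")
    p = 2.0 * min(np.count_nonzero(d <= 0), np.count_nonzero(d >= 0)) / n
    return float(min(1.0, max(p, 2.0 / n)))


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up correction.

    Returns ``(reject_flags, adjusted_p)`` with monotone adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
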