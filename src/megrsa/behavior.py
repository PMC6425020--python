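"""Behavioral similarity, MEG-behavior linkage, and task performance.

A multi-arrangement task yields per-subject item positions on screen; their
pairwise squared distances form a behavioral dissimilarity matrix.  The
behavioral RDM is correlated with the neural RDM at every time point
(partial Spearman, partialling the low-level feature confound), bracketed by
a between-subject noise ceiling, and decomposed by commonality analysis:
for each category model the drop in squared partial correlation between the
all-models-partialled and the leave-that-model-out-partialled coefficients
is the variance uniquely shared by neural data, behavior and that model.

1-back task performance is summarized as d' = z(hit) - z(false alarm) with
rates clipped by the 1/(2N) rule, mean RT over correct target trials, and
familiar-vs-unfamiliar paired two-sided Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, wilcoxon

from .core import GroupTimecourse, ModelRDM, RDMSeries
from .rsa import partial_spearman

__all__ = [
    "behavioral_rdm",
    "meg_behavior_correlation",
    "noise_ceiling",
    "commonality_analysis",
    "CommonalityTimecourse",
    "behavioral_performance",
    "PerformanceSummary",
]


def behavioral_rdm(positions: np.ndarray) -> ModelRDM:
    """Squared on-screen distances between arranged items.

    ``positions`` is ``[n_conditions, 2]``; returns a symmetric RDM with an
    undefined diagonal.  An arrangement with all items at one point is
    degenerate and rejected.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be [n_conditions, 2]")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    diff = positions[:, None, :] - positions[None, :, :]
    sq = (diff**2).sum(axis=2)
    rdm = ModelRDM(sq, name="behavior")
    if rdm.is_degenerate():
        raise ValueError("all items at identical positions; degenerate arrangement")
    return rdm


def meg_behavior_correlation(
    rdms: RDMSeries, behavior: ModelRDM, low_level: ModelRDM = None
) -> np.ndarray:
    """Partial Spearman between behavioral and neural RDMs per time point.

    One subject's time course; the low-level feature model (if given) is
    partialled out.  Group inference over subjects goes through the
    inference module with a chance level of 0.
    """
    if behavior.n_conditions != rdms.n_conditions:
        raise ValueError("behavioral RDM and neural RDMs must match in condition count")
    covs = [low_level] if low_level is not None else []
    data = rdms.vectors()
    bv = behavior.vector()
    out = np.empty(rdms.n_timepoints)
    for t in range(rdms.n_timepoints):
        out[t] = partial_spearman(data[t], bv, covs)
    return out


def noise_ceiling(rdm_vectors: list) -> tuple:
    """Upper and lower bounds on attainable model correlation.

    ``rdm_vectors`` holds one dissimilarity vector per subject.  Vectors are
    rank-transformed (Spearman convention, matching the analysis statistic);
    the upper bound averages each subject's correlation with the grand mean
    including the subject, the lower bound with the mean of the other
    subjects only.
    """
    vectors = [np.asarray(v, dtype=float).ravel() for v in rdm_vectors]
    n = len(vectors)
    if n < 3:
        raise ValueError("noise ceiling needs at least three subjects")
    length = vectors[0].size
    if any(v.size != length for v in vectors):
        raise ValueError("subject RDM vectors must have equal length")
    ranked = []
    for i, v in enumerate(vectors):
        if np.ptp(v) == 0:
            raise ValueError(f"subject {i} has a constant RDM vector")
        ranked.append(rankdata(v))
    R = np.vstack(ranked)
    grand = R.mean(axis=0)

    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / np.sqrt((a @ a) * (b @ b)))

    upper = float(np.mean([_corr(R[i], grand) for i in range(n)]))
    lower = float(
        np.mean([_corr(R[i], (grand * n - R[i]) / (n - 1)) for i in range(n)])
    )
    assert lower <= upper + 1e-12, "noise-ceiling bounds out of order"
    return lower, upper


@dataclass
class CommonalityTimecourse:
    """Commonality coefficients per model, plus the reference shared variance."""

    coefficients: dict          # model name -> [n_timepoints] (or [S, T] at group level)
    reference: np.ndarray       # squared MEG-behavior partial correlation (| low-level)
    times: np.ndarray
    window: tuple


def commonality_analysis(
    rdms: RDMSeries,
    behavior: ModelRDM,
    face_models: dict,
    low_level: ModelRDM = None,
    window=None,
    scale: str = "r2",
) -> CommonalityTimecourse:
    """Variance uniquely shared by neural data, behavior and each model.

    For each model ``m`` and time point the analysis computes the partial
    correlation between the neural and behavioral RDMs twice: once
    partialling every model (plus the low-level confound), once leaving
    ``m`` out.  The commonality coefficient is the difference on the
    squared-correlation (variance) scale, ``r_drop_m^2 - r_full^2``
    (``scale="r"`` reproduces the literal difference of coefficients).  The
    reference time course is the squared partial correlation given only the
    low-level confound — the total MEG-behavior shared variance the
    coefficients decompose.  ``window`` restricts the analysis (typically to
    the significant MEG-behavior interval); the familiarity model should not
    be among ``face_models`` here when its neural signature is late.
    """
    if scale not in ("r2", "r"):
        raise ValueError("scale must be 'r2' or 'r'")
    if window is None:
        mask = np.ones(rdms.n_timepoints, dtype=bool)
    else:
        mask = (rdms.times >= window[0]) & (rdms.times <= window[1])
        if not mask.any():
            raise ValueError(f"window {window} outside the analyzed times")
    times = rdms.times[mask]
    data = rdms.vectors()[mask]
    bv = behavior.vector()
    base_covs = [low_level] if low_level is not None else []
    all_models = list(face_models.values())

    coeffs = {name: np.empty(times.size) for name in face_models}
    reference = np.empty(times.size)
    for t in range(times.size):
        r_full = partial_spearman(data[t], bv, all_models + base_covs)
        reference[t] = partial_spearman(data[t], bv, base_covs) ** 2
        for name, model in face_models.items():
            rest = [m for m in all_models if m is not model]
            r_drop = partial_spearman(data[t], bv, rest + base_covs)
            if scale == "r2":
                coeffs[name][t] = r_drop**2 - r_full**2
            else:
                coeffs[name][t] = r_drop - r_full
    return CommonalityTimecourse(
        coefficients=coeffs,
        reference=reference,
        times=times,
        window=(float(times[0]), float(times[-1])),
    )


def _dprime(n_hit, n_target, n_fa, n_nontarget) -> float:
    """Sensitivity index with rates clipped away from {0, 1} by 1/(2N)."""
    hit = np.clip(n_hit / n_target, 1.0 / (2 * n_target), 1.0 - 1.0 / (2 * n_target))
    fa = np.clip(n_fa / n_nontarget, 1.0 / (2 * n_nontarget), 1.0 - 1.0 / (2 * n_nontarget))
    return float(norm.ppf(hit) - norm.ppf(fa))


def _signed_rank_p(x: np.ndarray, y: np.ndarray) -> float:
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(d, 0.0):
        return 1.0
    return float(wilcoxon(x, y, alternative="two-sided").pvalue)


@dataclass
class PerformanceSummary:
    """Group summary of 1-back task performance."""

    dprime: np.ndarray            # per subject
    rt_ms: np.ndarray             # per subject, correct target trials
    rt_familiar_ms: np.ndarray
    rt_unfamiliar_ms: np.ndarray
    dprime_familiar: np.ndarray
    dprime_unfamiliar: np.ndarray
    p_rt_familiarity: float
    p_dprime_familiarity: float

    @property
    def dprime_mean(self) -> float:
        return float(self.dprime.mean())

    @property
    def dprime_sem(self) -> float:
        return float(self.dprime.std(ddof=1) / np.sqrt(self.dprime.size))

    @property
    def rt_mean(self) -> float:
        return float(self.rt_ms.mean())

    @property
    def rt_sem(self) -> float:
        return float(self.rt_ms.std(ddof=1) / np.sqrt(self.rt_ms.size))


def behavioral_performance(trial_log: pd.DataFrame) -> PerformanceSummary:
    """Summarize a 1-back trial log.

    Expects columns ``subject, is_target, responded, rt_ms, familiarity``.
    Per subject: d' from hit and false-alarm counts (1/(2N) clipping), mean
    RT over correct target trials, and the familiar/unfamiliar split of
    both; across subjects: two-sided Wilcoxon signed-rank tests of the
    familiarity effect on RT and d'.
    """
    required = {"subject", "is_target", "responded", "rt_ms", "familiarity"}
    missing = required - set(trial_log.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    subjects = np.unique(trial_log["subject"])
    dp, rt, rt_f, rt_u, dp_f, dp_u = [], [], [], [], [], []
    for s in subjects:
        sub = trial_log[trial_log["subject"] == s]
        if not sub["is_target"].any():
            raise ValueError(f"subject {s} has no target trials")

        def _stats(frame):
            tgt = frame[frame["is_target"]]
            non = frame[~frame["is_target"]]
            d = _dprime(
                int(tgt["responded"].sum()), len(tgt), int(non["responded"].sum()), max(len(non), 1)
            )
            correct = tgt[tgt["responded"]]
            r = float(correct["rt_ms"].mean()) if len(correct) else np.nan
            return d, r

        d_all, r_all = _stats(sub)
        d_fam, r_fam = _stats(sub[sub["familiarity"] == "familiar"])
        d_unf, r_unf = _stats(sub[sub["familiarity"] == "unfamiliar"])
        dp.append(d_all)
        rt.append(r_all)
        dp_f.append(d_fam)
        dp_u.append(d_unf)
        rt_f.append(r_fam)
        rt_u.append(r_unf)
    dp, rt = np.asarray(dp), np.asarray(rt)
    rt_f, rt_u = np.asarray(rt_f), np.asarray(rt_u)
    dp_f, dp_u = np.asarray(dp_f), np.asarray(dp_u)
    return PerformanceSummary(
        dprime=dp,
        rt_ms=rt,
        rt_familiar_ms=rt_f,
        rt_unfamiliar_ms=rt_u,
        dprime_familiar=dp_f,
        dprime_unfamiliar=dp_u,
        p_rt_familiarity=_signed_rank_p(rt_f, rt_u),
        p_dprime_familiarity=_signed_rank_p(dp_f, dp_u),
    )
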