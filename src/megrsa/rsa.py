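"""Model RDMs and time-resolved partial rank correlation.

Category models are binary matrices (1 = between-category pair, 0 = within);
continuous feature models use 1 - Pearson correlation between per-condition
feature vectors.  The similarity statistic throughout is the partial
Spearman correlation: all vectors are rank-transformed (average ranks for
ties), data and target ranks are regressed on covariate ranks (with an
intercept, least-squares pseudo-inverse for rank-deficient covariate sets),
and the residuals are Pearson-correlated.  With no covariates this reduces
to the textbook Spearman coefficient.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .core import ConditionTable, GroupTimecourse, ModelRDM, RDMSeries

__all__ = [
    "make_model_rdm",
    "feature_rdm",
    "partial_spearman",
    "rsa_timecourse",
    "rsa_group_timecourses",
    "familiarity_split",
    "difference_timecourse",
    "distance_rdm",
]


def make_model_rdm(conditions: ConditionTable, factor: str) -> ModelRDM:
    """Binary category model: 1 where two conditions differ on ``factor``."""
    levels = conditions.factor(factor)
    if np.unique(levels).size < 2:
        raise ValueError(
            f"factor {factor!r} has a single level; a constant model cannot be correlated"
        )
    between = (levels[:, None] != levels[None, :]).astype(float)
    return ModelRDM(between, name=factor, condition_ids=conditions.condition_ids.copy())


def feature_rdm(features: np.ndarray, name: str = "features") -> ModelRDM:
    """Continuous model: 1 - Pearson correlation between feature vectors.

    ``features`` is ``[n_conditions, n_features]``; entries range over
    [0, 2].  Raises for constant per-condition feature vectors, naming the
    offending conditions.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("features must be [n_conditions, n_features] with >= 2 features")
    sd = features.std(axis=1)
    constant = np.where(sd == 0)[0]
    if constant.size:
        raise ValueError(f"constant feature vectors for conditions: {constant.tolist()}")
    corr = np.corrcoef(features)
    return ModelRDM(1.0 - corr, name=name)


def _as_vector(x) -> np.ndarray:
    if isinstance(x, ModelRDM):
        return x.vector()
    return np.asarray(x, dtype=float).ravel()


def partial_spearman(x, y, covariates=()) -> float:
    """Partial Spearman correlation of ``x`` and ``y`` given ``covariates``.

    Inputs are vectorized lower triangles (arrays or :class:`ModelRDM`).
    Vectors that end up exactly in the covariate span (zero residual) carry
    no rankable variance and return 0.0 with a warning; constant *input*
    vectors are an error.
    """
    xv = _as_vector(x)
    yv = _as_vector(y)
    covs = [_as_vector(c) for c in covariates]
    n = xv.size
    if yv.size != n or any(c.size != n for c in covs):
        raise ValueError("all vectors must have the same length")
    for v, label in [(xv, "x"), (yv, "y")] + [(c, f"covariate {i}") for i, c in enumerate(covs)]:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in {label}")
        if np.ptp(v) == 0:
            raise ValueError(f"{label} is constant; rank correlation undefined")
    rx = rankdata(xv)
    ry = rankdata(yv)
    if not covs:
        resid_x, resid_y = rx - rx.mean(), ry - ry.mean()
    else:
        Z = np.column_stack([np.ones(n)] + [rankdata(c) for c in covs])
        # pseudo-inverse tolerates duplicated / rank-deficient covariates
        proj = Z @ np.linalg.pinv(Z)
        resid_x = rx - proj @ rx
        resid_y = ry - proj @ ry
    sx = np.sqrt(resid_x @ resid_x)
    sy = np.sqrt(resid_y @ resid_y)
    tiny = 1e-10 * n
    if sx < tiny or sy < tiny:
        warnings.warn(
            "zero residual variance after partialling covariates; returning 0.0",
            stacklevel=2,
        )
        return 0.0
    return float((resid_x @ resid_y) / (sx * sy))


def rsa_timecourse(
    rdms: RDMSeries,
    target: ModelRDM,
    covariates=(),
    low_level: ModelRDM = None,
) -> np.ndarray:
    """Partial Spearman between data RDMs and a target model per time point.

    ``covariates`` are the competing category models to partial out; the
    optional ``low_level`` confound model (e.g. an image-computable feature
    RDM) is always appended to the covariate set.  Returns one coefficient
    per time point for a single subject.
    """
    covs = list(covariates)
    if low_level is not None:
        covs.append(low_level)
    data = rdms.vectors()
    tv = target.vector()
    if np.ptp(tv) == 0:
        raise ValueError(f"target model {target.name!r} is constant")
    n = tv.size
    # covariate ranks do not change over time: build the rank-space projector
    # once and sweep it over all time points (same arithmetic as
    # partial_spearman, vectorized)
    ry = rankdata(tv)
    if covs:
        Z = np.column_stack([np.ones(n)] + [rankdata(_as_vector(c)) for c in covs])
        pinv = np.linalg.pinv(Z)
        resid_y = ry - Z @ (pinv @ ry)
    else:
        Z = pinv = None
        resid_y = ry - ry.mean()
    sy = np.sqrt(resid_y @ resid_y)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in the data RDMs")
    if np.any(np.ptp(data, axis=1) == 0):
        bad = rdms.times[np.ptp(data, axis=1) == 0]
        raise ValueError(f"constant data RDM at t={bad.tolist()} ms")
    rx = rankdata(data, axis=1)
    if Z is not None:
        resid_x = rx - (rx @ pinv.T) @ Z.T
    else:
        resid_x = rx - rx.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.einsum("ij,ij->i", resid_x, resid_x))
    tiny = 1e-10 * n
    out = np.zeros(rdms.n_timepoints)
    ok = (sx >= tiny) & (sy >= tiny)
    out[ok] = (resid_x[ok] @ resid_y) / (sx[ok] * sy)
    return out


def rsa_group_timecourses(
    subject_rdms: list,
    models: dict,
    low_level: ModelRDM = None,
    include_other_models: bool = True,
) -> dict:
    """Per-model group time courses across subjects.

    ``models`` maps name -> :class:`ModelRDM`.  For each target model the
    remaining models act as covariates (plus the low-level confound), per the
    partial-correlation design; set ``include_other_models=False`` to
    correlate each model alone (still partialling the confound).
    """
    out = {}
    times = subject_rdms[0].times
    for name, target in models.items():
        covs = [m for key, m in models.items() if key != name] if include_other_models else []
        rows = [rsa_timecourse(r, target, covs, low_level) for r in subject_rdms]
        out[name] = GroupTimecourse(np.vstack(rows), times, chance_level=0.0, name=name)
    return out


def familiarity_split(rdms: RDMSeries, conditions: ConditionTable):
    """Restrict an RDM series to familiar-only and unfamiliar-only conditions.

    Returns ``(familiar_series, unfamiliar_series, familiar_table,
    unfamiliar_table)``.  Model RDMs for subset analyses should be rebuilt
    from (or subset to) the returned tables; the familiarity model itself is
    constant within each subset and must be excluded there.
    """
    fam = conditions.factor("familiarity")
    levels = np.unique(fam)
    if levels.size != 2:
        raise ValueError("familiarity must have exactly two levels")
    fam_mask = fam == "familiar"
    return (
        rdms.subset(fam_mask),
        rdms.subset(~fam_mask),
        conditions.subset(fam_mask),
        conditions.subset(~fam_mask),
    )


def difference_timecourse(tc_a: GroupTimecourse, tc_b: GroupTimecourse) -> GroupTimecourse:
    """Per-subject, per-timepoint difference ``a - b`` (chance level 0)."""
    if tc_a.data.shape != tc_b.data.shape:
        raise ValueError("time courses must have matching subjects and time axes")
    if not np.allclose(tc_a.times, tc_b.times):
        raise ValueError("time axes differ")
    return GroupTimecourse(
        tc_a.data - tc_b.data,
        tc_a.times.copy(),
        chance_level=0.0,
        name=f"{tc_a.name}-minus-{tc_b.name}" if tc_a.name or tc_b.name else "",
    )


def distance_rdm(patterns: np.ndarray, name: str = "distance") -> ModelRDM:
    """Squared-Euclidean-distance RDM between condition patterns.

    Convenience for noise-free analyses: ``patterns`` is
    ``[n_conditions, n_features]``.
    """
    patterns = np.asarray(patterns, dtype=float)
    sq = ((patterns[:, None, :] - patterns[None, :, :]) ** 2).sum(axis=2)
    return ModelRDM(sq, name=name)
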