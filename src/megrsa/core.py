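"""Core data containers shared across the analysis stages.

Every container is a thin, validated wrapper around numpy arrays plus the
metadata the downstream stages need (time axes in milliseconds, condition
labels, validity flags).  Containers are immutable by convention: operations
return new instances rather than mutating in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConditionTable",
    "Epochs",
    "ComponentEpochs",
    "RDMSeries",
    "ModelRDM",
    "GroupTimecourse",
    "ClusterResult",
    "LatencyEstimate",
    "lower_triangle",
    "square_from_lower_triangle",
]

#: Columns a condition table must carry.  ``condition_id`` indexes rows of
#: RDMs; the factor columns define the category models.
CONDITION_COLUMNS = ("condition_id", "identity", "image", "gender", "age", "familiarity")


class ConditionTable:
    """Design table mapping each condition to its factor levels.

    Wraps a :class:`pandas.DataFrame` with one row per condition and columns
    ``condition_id, identity, image, gender, age, familiarity`` (extra columns
    are allowed and may be used as custom model factors).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CONDITION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"condition table missing columns: {missing}")
        if frame["condition_id"].duplicated().any():
            raise ValueError("condition_id values must be unique")
        self.frame = frame.reset_index(drop=True)

    @property
    def n_conditions(self) -> int:
        return len(self.frame)

    @property
    def condition_ids(self) -> np.ndarray:
        return self.frame["condition_id"].to_numpy()

    def factor(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"unknown factor {name!r}; available: {list(self.frame.columns)}")
        return self.frame[name].to_numpy()

    def subset(self, mask: np.ndarray) -> "ConditionTable":
        return ConditionTable(self.frame.loc[np.asarray(mask)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"ConditionTable({self.n_conditions} conditions)"


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a 1-D vector")
    if times.size == 1:
        return times
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("times must have a uniform step")
    return times


@dataclass
class Epochs:
    """Epoched multichannel trial data.

    data
        ``[n_trials, n_channels, n_timepoints]`` array (units arbitrary;
        femtotesla for real MEG recordings).
    times
        Time axis in milliseconds relative to stimulus onset.
    condition_id
        Per-trial condition label indexing a :class:`ConditionTable`.
    valid
        Per-trial flag; invalid trials are kept in place but excluded from
        every downstream computation.
    """

    data: np.ndarray
    times: np.ndarray
    condition_id: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be [n_trials, n_channels, n_timepoints]")
        self.times = _check_times(self.times)
        if self.times.size != self.data.shape[2]:
            raise ValueError("times length must match the last data axis")
        self.condition_id = np.asarray(self.condition_id)
        if self.condition_id.shape != (self.data.shape[0],):
            raise ValueError("condition_id must have one entry per trial")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.data.shape[0],):
            raise ValueError("valid must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def time_step(self) -> float:
        return float(self.times[1] - self.times[0])

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def check_conditions(self, conditions: ConditionTable) -> None:
        known = set(conditions.condition_ids.tolist())
        present = set(np.unique(self.condition_id).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"condition ids not in the condition table: {sorted(unknown)}")

    def replace(self, **kwargs) -> "Epochs":
        return replace(self, **kwargs)


@dataclass
class ComponentEpochs:
    """Epochs projected onto principal components.

    ``data`` is ``[n_trials, n_components, n_timepoints]``; ``loadings`` maps
    channels to components; ``explained_variance_fraction`` gives each
    component's share of total variance.
    """

    data: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    times: np.ndarray
    condition_id: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = _check_times(self.times)
        self.condition_id = np.asarray(self.condition_id)
        self.valid = np.asarray(self.valid, dtype=bool)
        n_comp = self.data.shape[1]
        if self.loadings.shape[1] != n_comp:
            raise ValueError("loadings must have one column per component")
        if len(self.explained_variance_fraction) != n_comp:
            raise ValueError("explained_variance_fraction must have one entry per component")

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - t_ms)))


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries of a square matrix as a vector."""
    matrix = np.asarray(matrix)
    i, j = np.tril_indices(matrix.shape[-1], k=-1)
    return matrix[..., i, j]


def square_from_lower_triangle(vec: np.ndarray, n: int, diag=np.nan) -> np.ndarray:
    """Rebuild a symmetric matrix (undefined diagonal) from its lower triangle."""
    out = np.full(vec.shape[:-1] + (n, n), diag, dtype=float)
    i, j = np.tril_indices(n, k=-1)
    out[..., i, j] = vec
    out[..., j, i] = vec
    return out


@dataclass
class RDMSeries:
    """Time-indexed stack of symmetric condition x condition dissimilarities.

    ``values`` is ``[n_timepoints, n_conditions, n_conditions]``; the diagonal
    is undefined and stored as NaN.  Entries are cross-validated pairwise
    decoding accuracies in [0, 1] unless another dissimilarity is used.
    """

    values: np.ndarray
    times: np.ndarray
    condition_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be [n_timepoints, n, n]")
        self.times = _check_times(self.times)
        if self.times.size != self.values.shape[0]:
            raise ValueError("times length must match the first axis of values")
        self.condition_ids = np.asarray(self.condition_ids)
        if self.condition_ids.size != self.values.shape[1]:
            raise ValueError("one condition id per RDM row required")
        upper = np.swapaxes(self.values, 1, 2)
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(upper), atol=1e-12, rtol=0
        ):
            raise ValueError("RDMs must be symmetric at every time point")
        # force undefined diagonal
        idx = np.arange(self.values.shape[1])
        self.values[:, idx, idx] = np.nan

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def vectors(self) -> np.ndarray:
        """Lower-triangle vectors, shape ``[n_timepoints, n_pairs]``."""
        return lower_triangle(self.values)

    def mean_dissimilarity(self) -> np.ndarray:
        """Per-timepoint mean of the strictly-lower-triangle entries."""
        return self.vectors().mean(axis=1)

    def subset(self, mask: np.ndarray) -> "RDMSeries":
        mask = np.asarray(mask, dtype=bool)
        vals = self.values[:, mask][:, :, mask]
        return RDMSeries(vals.copy(), self.times.copy(), self.condition_ids[mask].copy())

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - t_ms)))


@dataclass
class ModelRDM:
    """Condition x condition predictor matrix for representational analysis.

    Binary category models contain 1 for between-category and 0 for
    within-category pairs; continuous models hold feature dissimilarities.
    The diagonal is undefined (NaN).
    """

    values: np.ndarray
    name: str
    condition_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("model RDM must be square")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12, rtol=0
        ):
            raise ValueError("model RDM must be symmetric")
        if self.condition_ids is None:
            self.condition_ids = np.arange(self.values.shape[0])
        self.condition_ids = np.asarray(self.condition_ids)
        idx = np.arange(self.values.shape[0])
        self.values[idx, idx] = np.nan

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        return lower_triangle(self.values)

    def subset(self, mask: np.ndarray) -> "ModelRDM":
        mask = np.asarray(mask, dtype=bool)
        vals = self.values[mask][:, mask].copy()
        return ModelRDM(vals, self.name, self.condition_ids[mask].copy())

    def is_degenerate(self) -> bool:
        v = self.vector()
        return bool(np.nanmax(v) == np.nanmin(v))


@dataclass
class GroupTimecourse:
    """Per-subject time courses of one statistic, ready for group inference.

    ``data`` is ``[n_subjects, n_timepoints]``.  ``chance_level`` is 0.5 for
    decoding accuracies and 0 for correlations, correlation differences and
    commonality coefficients; inference always centers by it first.
    """

    data: np.ndarray
    times: np.ndarray
    chance_level: float = 0.0
    name: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = _check_times(self.times)
        if self.data.shape[1] != self.times.size:
            raise ValueError("data must be [n_subjects, n_timepoints]")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class ClusterResult:
    """Outcome of a cluster-based sign-permutation test."""

    significant: np.ndarray                 # per-timepoint bool, cluster-corrected
    clusters: list                          # list of dicts: start_ms, end_ms, length, p_value
    pointwise_threshold: np.ndarray         # per-timepoint cluster-inducing threshold
    suprathreshold: np.ndarray              # per-timepoint bool, uncorrected
    cluster_length_threshold: int
    n_permutations: int
    times: np.ndarray = None
    seed: int = None

    def onset_ms(self) -> float:
        """Earliest cluster-corrected significant time strictly after 0 ms."""
        post = (self.times > 0) & self.significant
        if not post.any():
            return np.nan
        return float(self.times[np.argmax(post)])

    def to_dict(self) -> dict:
        return {
            "clusters": self.clusters,
            "cluster_length_threshold": int(self.cluster_length_threshold),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
        }


@dataclass
class LatencyEstimate:
    """Bootstrap onset and peak latency estimates with 95% CIs."""

    onset_ms: float
    onset_ci: tuple
    peak_ms: float
    peak_ci: tuple
    peak_window: tuple
    n_bootstrap: int
    n_missing_onset: int = 0
    onset_samples: np.ndarray = field(default=None, repr=False)
    peak_samples: np.ndarray = field(default=None, repr=False)
    onset_reportable: bool = True

    def to_dict(self) -> dict:
        return {
            "onset_ms": None if np.isnan(self.onset_ms) else float(self.onset_ms),
            "onset_ci": [float(x) for x in self.onset_ci] if self.onset_reportable else None,
            "peak_ms": float(self.peak_ms),
            "peak_ci": [float(x) for x in self.peak_ci],
            "peak_window": [float(x) for x in self.peak_window],
            "n_bootstrap": int(self.n_bootstrap),
            "n_missing_onset": int(self.n_missing_onset),
            "onset_reportable": bool(self.onset_reportable),
        }
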