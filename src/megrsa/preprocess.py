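"""Trial-level cleaning and dimensionality reduction.

The canonical order is baseline correction -> peak-to-peak trial rejection ->
zero-phase low-pass smoothing -> PCA to component space.  Each step is a pure
function of its input plus configuration and returns a new object.

The low-pass stage uses a zero-phase FIR filter (windowed-sinc design applied
forward and backward), so it preserves the DC component and introduces no
phase delay; results should be robust to disabling it, and the reduction
stage accepts either filtered or unfiltered epochs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .core import ComponentEpochs, Epochs

__all__ = [
    "baseline_correct",
    "reject_bad_trials",
    "lowpass_smooth",
    "reduce_dimensions",
    "preprocess_epochs",
]


def _window_slice(times: np.ndarray, window) -> np.ndarray:
    start, end = float(window[0]), float(window[1])
    if start >= end:
        raise ValueError("baseline window start must precede end")
    mask = (times >= start) & (times <= end)
    if not mask.any():
        raise ValueError(f"window [{start}, {end}] ms contains no samples")
    return mask


def baseline_correct(epochs: Epochs, window=(-200.0, 0.0)) -> Epochs:
    """Subtract each trial's and channel's mean over the baseline window."""
    mask = _window_slice(epochs.times, window)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.replace(data=epochs.data - base)


def reject_bad_trials(epochs: Epochs, threshold: float) -> Epochs:
    """Flag trials whose peak-to-peak range on any channel exceeds ``threshold``.

    The trial count is preserved; only the ``valid`` flags change (already
    invalid trials stay invalid).  Raises if no valid trial survives.
    """
    if threshold <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)   # [trials, channels]
    bad = (p2p > threshold).any(axis=1)
    valid = epochs.valid & ~bad
    if not valid.any():
        raise ValueError(
            f"all trials rejected at peak-to-peak threshold {threshold}; "
            "threshold too strict for this data"
        )
    return epochs.replace(valid=valid)


def _fir_lowpass(cutoff_hz: float, fs_hz: float, numtaps: int) -> np.ndarray:
    return signal.firwin(numtaps, cutoff_hz, fs=fs_hz)


def lowpass_smooth(epochs: Epochs, cutoff_hz: float = 30.0, numtaps: int = 37) -> Epochs:
    """Zero-phase FIR low-pass per trial and channel.

    The windowed-sinc (Hamming) kernel is applied forward and backward
    (``filtfilt``), squaring its magnitude response; ``numtaps`` controls the
    transition width.  The DC component is preserved exactly up to edge
    effects.  Raises if the cutoff is at or above Nyquist.
    """
    fs = 1000.0 / epochs.time_step
    if cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency {fs / 2} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    taps = min(numtaps, max(3, 2 * (epochs.n_timepoints // 3) - 1))
    if taps % 2 == 0:
        taps -= 1
    kernel = _fir_lowpass(cutoff_hz, fs, taps)
    padlen = min(3 * taps, epochs.n_timepoints - 1)
    data = signal.filtfilt(kernel, [1.0], epochs.data, axis=2, padtype="even", padlen=padlen)
    return epochs.replace(data=data)


def reduce_dimensions(epochs: Epochs, variance_retained: float = 0.9999) -> ComponentEpochs:
    """Project channels onto the principal components of the whole recording.

    The decomposition is fitted per subject on the concatenation of every
    valid trial and time point (samples = trials x timepoints, features =
    channels), never per time point.  The smallest component count whose
    cumulative explained variance reaches ``variance_retained`` is kept, all
    trials (valid and invalid) are projected, and component scores are
    re-baseline-corrected over the pre-stimulus window.
    """
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must be in (0, 1]")
    valid_data = epochs.data[epochs.valid]
    if valid_data.shape[0] == 0:
        raise ValueError("no valid trials to fit the decomposition on")
    n_trials_v, n_channels, n_times = valid_data.shape
    samples = valid_data.transpose(0, 2, 1).reshape(-1, n_channels)
    pca = PCA(svd_solver="full")
    pca.fit(samples)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    n_keep = min(n_keep, len(cum))
    loadings = pca.components_[:n_keep].T            # [channels, components]
    center = pca.mean_

    flat = epochs.data.transpose(0, 2, 1).reshape(-1, n_channels)
    scores = (flat - center) @ loadings
    scores = scores.reshape(epochs.n_trials, n_times, n_keep).transpose(0, 2, 1)

    pre = epochs.times <= 0
    if pre.any():
        scores = scores - scores[:, :, pre].mean(axis=2, keepdims=True)
    return ComponentEpochs(
        data=scores,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_[:n_keep],
        times=epochs.times.copy(),
        condition_id=epochs.condition_id.copy(),
        valid=epochs.valid.copy(),
    )


def preprocess_epochs(
    epochs: Epochs,
    baseline_window=(-200.0, 0.0),
    p2p_threshold: float = None,
    lowpass_hz: float = 30.0,
    variance_retained: float = 0.9999,
    apply_lowpass: bool = True,
) -> ComponentEpochs:
    """Full per-subject preprocessing chain with the canonical step order."""
    out = baseline_correct(epochs, baseline_window)
    if p2p_threshold is not None:
        out = reject_bad_trials(out, p2p_threshold)
    if apply_lowpass and lowpass_hz is not None:
        out = lowpass_smooth(out, lowpass_hz)
    return reduce_dimensions(out, variance_retained)
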