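"""xDAWN spatial filtering for evoked-response enhancement.

The signal model is ``X = D·A + N``: the continuous recording ``X``
(channels × samples) contains an evoked epoch ``A`` (epoch-length × channels)
entering at each evoked-stimulus onset through a 0/1 Toeplitz design ``D``
(samples × epoch-length), plus everything else ``N``.  The evoked estimate is
the (ridge-stabilised) least-squares solution

    Â = (DᵀD + εI)⁻¹ Dᵀ Xᵀ,

and spatial filters ``w`` maximise the evoked-to-total energy ratio

    (wᵀ Âᵀ DᵀD Â w) / (wᵀ X Xᵀ w),

a symmetric generalized eigenproblem.  Eigenvalues are therefore bounded by
1 under this signal-to-total normalisation.  Forward patterns
``Σ W (Wᵀ Σ W)⁻¹`` give the field-map counterpart of each filter for
topographic inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .preprocess import EpochSet


@dataclass
class DesignMatrix:
    """Toeplitz-structured 0/1 design: column j marks onset-sample + j."""

    onsets: np.ndarray  # sample indices of evoked events
    n_samples: int
    epoch_len: int

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if len(self.onsets) and (
            self.onsets.min() < 0 or self.onsets.max() >= self.n_samples
        ):
            raise ValueError("onsets must lie within the signal")

    def toarray(self) -> np.ndarray:
        D = np.zeros((self.n_samples, self.epoch_len))
        for onset in self.onsets:
            stop = min(onset + self.epoch_len, self.n_samples)
            D[onset + np.arange(stop - onset), np.arange(stop - onset)] += 1.0
        return D


def build_design(onsets, n_samples: int, epoch_len: int) -> DesignMatrix:
    """Design matrix for evoked events at the given onset samples."""
    return DesignMatrix(onsets=np.asarray(onsets, int), n_samples=n_samples,
                        epoch_len=epoch_len)


@dataclass
class SpatialFilter:
    """Fitted xDAWN filter bank.

    ``weights`` (channels × components) project data onto pseudo-channels;
    ``eigenvalues`` are the evoked-to-total ratio scores in descending order;
    ``patterns`` are the forward field maps of each component.
    """

    weights: np.ndarray
    eigenvalues: np.ndarray
    patterns: np.ndarray
    channel_labels: tuple
    n_components: int
    fitted_on: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_labels):
            row = {"channel": ch}
            for k in range(self.n_components):
                row[f"weight_{k + 1}"] = self.weights[ci, k]
                row[f"pattern_{k + 1}"] = self.patterns[ci, k]
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.attrs["eigenvalues"] = list(self.eigenvalues)
        return frame

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        for k, ev in enumerate(self.eigenvalues, start=1):
            frame[f"eigenvalue_{k}"] = ev
        frame.to_csv(path, sep="\t", index=False)


def fit_xdawn(
    signal: np.ndarray,
    design: DesignMatrix,
    n_components: int,
    ridge: float = 1e-6,
    channel_labels=None,
    fitted_on: dict | None = None,
) -> SpatialFilter:
    """Estimate xDAWN filters from a continuous signal and evoked design.

    ``ridge`` is trace-scaled: the actual stabiliser is
    ``ridge × trace(DᵀD)/epoch_len``.
    """
    signal = np.asarray(signal, dtype=float)
    n_channels, n_samples = signal.shape
    if design.n_samples != n_samples:
        raise ValueError("design and signal sample counts differ")
    if not 1 <= n_components <= n_channels:
        raise ValueError("n_components must be in [1, n_channels]")

    D = design.toarray()
    DtD = D.T @ D
    eps = ridge * np.trace(DtD) / design.epoch_len if ridge else 0.0
    try:
        A_hat = scipy.linalg.solve(
            DtD + eps * np.eye(design.epoch_len), D.T @ signal.T, assume_a="pos"
        )
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise np.linalg.LinAlgError(
            "DᵀD is rank-deficient; refit with ridge > 0"
        ) from err

    evoked_cov = A_hat.T @ DtD @ A_hat  # channels × channels
    total_cov = signal @ signal.T
    if ridge:
        # trace-scaled stabiliser keeps the pencil solvable for rank-deficient
        # totals (e.g. the pure-evoked, zero-noise limit)
        total_cov = total_cov + (
            ridge * np.trace(total_cov) / n_channels
        ) * np.eye(n_channels)
    else:
        # the pencil needs a positive-definite total covariance
        spectrum = np.linalg.eigvalsh(total_cov)
        if spectrum[0] <= 1e-12 * max(spectrum[-1], 1e-300):
            raise np.linalg.LinAlgError(
                "total covariance is singular; add noise, channels, or ridge > 0"
            )
    try:
        eigvals, eigvecs = scipy.linalg.eigh(evoked_cov, total_cov)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise np.linalg.LinAlgError(
            "total covariance is singular; add noise, channels, or ridge > 0"
        ) from err
    order = np.argsort(eigvals)[::-1][:n_components]
    weights = eigvecs[:, order]
    eigenvalues = eigvals[order]

    # sign convention: the component's evoked peak within the epoch is positive
    evoked = A_hat @ weights  # epoch_len × components
    for k in range(weights.shape[1]):
        peak = evoked[np.argmax(np.abs(evoked[:, k])), k]
        if peak < 0:
            weights[:, k] = -weights[:, k]

    covariance = total_cov / n_samples
    patterns = forward_patterns(weights, covariance)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i + 1}" for i in range(n_channels))
    return SpatialFilter(
        weights=weights,
        eigenvalues=eigenvalues,
        patterns=patterns,
        channel_labels=tuple(channel_labels),
        n_components=n_components,
        fitted_on=fitted_on,
    )


def fit_xdawn_epochs(
    epochs: EpochSet,
    evoked_class: str,
    n_components: int,
    ridge: float = 1e-6,
    fitted_on: dict | None = None,
) -> SpatialFilter:
    """Fit xDAWN on an epoch set re-assembled as a continuous block.

    Trials are concatenated along time; evoked-class trials contribute an
    onset at their first sample.  This preserves the Toeplitz least-squares
    formulation while respecting training-fold boundaries.
    """
    n_trials, n_channels, n_samples = epochs.data.shape
    signal = np.transpose(epochs.data, (1, 0, 2)).reshape(n_channels, -1)
    onsets = np.flatnonzero(epochs.labels == evoked_class) * n_samples
    if len(onsets) == 0:
        raise ValueError(f"no trials of evoked class {evoked_class!r}")
    design = build_design(onsets, n_trials * n_samples, n_samples)
    return fit_xdawn(
        signal, design, n_components, ridge,
        channel_labels=epochs.channel_labels, fitted_on=fitted_on,
    )


def apply_filter(epochs: EpochSet, filt: SpatialFilter) -> EpochSet:
    """Project epochs onto the filter bank's pseudo-channels."""
    if tuple(epochs.channel_labels) != tuple(filt.channel_labels):
        raise ValueError("epoch channel order does not match the fitted filter")
    data = np.einsum("ck,tcs->tks", filt.weights, epochs.data)
    labels = tuple(f"xd{k + 1}" for k in range(filt.n_components))
    return EpochSet(
        data=data,
        rate=epochs.rate,
        t0_offset_ms=epochs.t0_offset_ms,
        channel_labels=labels,
        labels=epochs.labels,
        event_index=epochs.event_index,
        subject=epochs.subject,
        condition=epochs.condition,
    )


def forward_patterns(weights: np.ndarray, covariance: np.ndarray,
                     normalize: bool = True) -> np.ndarray:
    """Forward model ``Σ W (Wᵀ Σ W)⁻¹`` of a filter bank.

    With ``normalize=True`` each pattern column is scaled to unit Euclidean
    norm, making the maps invariant to positive rescaling of the filters.
    """
    weights = np.asarray(weights, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    patterns = covariance @ weights @ np.linalg.inv(weights.T @ covariance @ weights)
    if normalize:
        norms = np.linalg.norm(patterns, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        patterns = patterns / norms
    return patterns
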