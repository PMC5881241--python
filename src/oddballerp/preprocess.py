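"""Preprocessing: continuous recordings → clean, labeled epoch sets.

Two branches are supported, mirroring how offline ERP work and single-trial
decoding treat the same raw data differently:

* **ERP branch** (:func:`erp_branch`): common-average re-reference, 0.1–30 Hz
  band-pass, −100..1000 ms segments, optional prestimulus baseline
  correction, amplitude/gradient artifact rejection (±100 µV, 75 µV/sample).
* **Classification branch** (:func:`clf_branch`): 0–1 s segments at the
  acquisition reference, per-channel zero-mean, decimation to 25 Hz, then a
  0.1–4 Hz band-pass.  Artifact decisions are *reused* from the ERP branch so
  both analyses see the same trials.

All filters are zero-phase (forward–backward 4th-order Butterworth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EventList, Recording


@dataclass
class EpochSet:
    """Trials × channels × samples block with per-trial labels.

    ``t0_offset_ms`` is the time of the first sample relative to stimulus
    onset; ``event_index`` maps each trial back to its row in the source
    :class:`~oddballerp.io.EventList`.
    """

    data: np.ndarray
    rate: float
    t0_offset_ms: float
    channel_labels: tuple
    labels: np.ndarray
    event_index: np.ndarray = None
    subject: str | None = None
    condition: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be trials × channels × samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel label count must equal channel axis")
        if self.event_index is None:
            self.event_index = np.arange(self.data.shape[0])
        self.event_index = np.asarray(self.event_index, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.n_samples) * 1000.0 / self.rate

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self, data=self.data[mask], labels=self.labels[mask],
            event_index=self.event_index[mask],
        )

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy())


@dataclass
class RejectionReport:
    """Per-trial rejection decisions with the violated rule and worst sample."""

    frame: pd.DataFrame  # columns: event_index, label, kept, rule, worst_channel, worst_value

    @property
    def kept_mask(self) -> np.ndarray:
        return self.frame["kept"].to_numpy(dtype=bool)

    @property
    def kept_event_index(self) -> np.ndarray:
        return self.frame.loc[self.frame["kept"], "event_index"].to_numpy(dtype=int)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _apply_sos(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    n = data.shape[-1]
    padlen = min(3 * 2 * sos.shape[0], n - 1)
    return sps.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def bandpass(obj, low: float, high: float, order: int = 4):
    """Zero-phase Butterworth band-pass; works on Recording or EpochSet."""
    if not 0 < low < high < obj.rate / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz infeasible at rate {obj.rate} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=obj.rate, output="sos")
    return replace(obj, data=_apply_sos(obj.data, sos))


def rereference_average(recording: Recording) -> Recording:
    """Common-average re-reference, re-instating the implicit reference channel.

    The acquisition reference (FCz) is an all-zero channel by construction; it
    is appended before averaging so the common average is taken over the full
    electrode set, then appears as a regular (generally non-zero) channel in
    the output.
    """
    full = np.vstack([recording.data, np.zeros((1, recording.n_samples))])
    full = full - full.mean(axis=0, keepdims=True)
    return Recording(
        data=full,
        rate=recording.rate,
        channel_labels=recording.channel_labels + (recording.reference_label,),
        reference_label="average",
    )


def epoch(recording: Recording, events: EventList, tmin_ms: float, tmax_ms: float,
          subject: str | None = None, condition: str | None = None) -> EpochSet:
    """Cut half-open windows [onset+tmin, onset+tmax) around each event.

    Events whose window falls outside the recording are dropped with a
    warning.  Sample indices floor toward zero, so epoching commutes with
    shifting recording and events together.
    """
    if tmin_ms >= tmax_ms:
        raise ValueError("tmin_ms must be < tmax_ms")
    rate = recording.rate
    n_samp = int(round(rate * (tmax_ms - tmin_ms) / 1000.0))
    trials, labels, kept_idx = [], [], []
    dropped = 0
    for i, (onset, cls) in enumerate(zip(events.onset_ms, events.stim_class)):
        start = int((onset + tmin_ms) * rate / 1000.0)
        if start < 0 or start + n_samp > recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.data[:, start : start + n_samp])
        labels.append(cls)
        kept_idx.append(i)
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) with windows outside the recording",
                      stacklevel=2)
    data = (np.stack(trials) if trials
            else np.empty((0, recording.n_channels, n_samp)))
    return EpochSet(
        data=data, rate=rate, t0_offset_ms=tmin_ms,
        channel_labels=recording.channel_labels,
        labels=np.asarray(labels, dtype=object),
        event_index=np.asarray(kept_idx, dtype=int),
        subject=subject if subject is not None else events.subject,
        condition=condition if condition is not None else events.condition,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of the prestimulus (t < 0) samples per trial/channel."""
    pre = epochs.times_ms() < 0
    if not pre.any():
        raise ValueError("no prestimulus samples to baseline on")
    base = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_artifacts(
    epochs: EpochSet, amp_uv: float = 100.0, grad_uv: float = 75.0
) -> tuple[EpochSet, RejectionReport]:
    """Reject trials violating the amplitude (±amp) or gradient rule.

    Gradient = absolute first difference between adjacent samples at the
    branch's current sampling rate (µV per sampling step).
    """
    if amp_uv <= 0 or grad_uv <= 0:
        raise ValueError("thresholds must be positive")
    rows = []
    for t in range(epochs.n_trials):
        trial = epochs.data[t]
        absmax = np.abs(trial)
        amp_ch, amp_s = np.unravel_index(np.argmax(absmax), absmax.shape)
        amp_worst = trial[amp_ch, amp_s]
        grads = np.abs(np.diff(trial, axis=1))
        if grads.size:
            g_ch, g_s = np.unravel_index(np.argmax(grads), grads.shape)
            grad_worst = grads[g_ch, g_s]
        else:
            g_ch, grad_worst = 0, 0.0
        if abs(amp_worst) > amp_uv:
            kept, rule, ch, worst = False, "amplitude", amp_ch, amp_worst
        elif grad_worst > grad_uv:
            kept, rule, ch, worst = False, "gradient", g_ch, grad_worst
        else:
            kept, rule, ch, worst = True, "", amp_ch, amp_worst
        rows.append(
            {
                "event_index": int(epochs.event_index[t]),
                "label": epochs.labels[t],
                "kept": kept,
                "rule": rule,
                "worst_channel": epochs.channel_labels[ch],
                "worst_value": float(worst),
            }
        )
    report = RejectionReport(pd.DataFrame(
        rows, columns=["event_index", "label", "kept", "rule",
                       "worst_channel", "worst_value"]))
    return epochs.select_trials(report.kept_mask), report


def mark_successful_targets(
    events: EventList, min_ms: float = 200.0, max_ms: float = 2000.0
) -> EventList:
    """Flag targets answered within [min_ms, max_ms] after onset as successful."""
    out = events.copy()
    is_target = out.stim_class == "target"
    with np.errstate(invalid="ignore"):
        in_window = (out.response_ms >= min_ms) & (out.response_ms <= max_ms)
    out.successful = is_target & np.nan_to_num(in_window, nan=False).astype(bool)
    return out


def zero_mean(epochs: EpochSet) -> EpochSet:
    """Normalise each trial and channel to zero mean over the epoch."""
    return replace(epochs, data=epochs.data - epochs.data.mean(axis=2, keepdims=True))


def decimate(obj, target_rate: float = 25.0, order: int = 8):
    """Anti-alias lowpass (cutoff 0.4 × target rate) then integer subsampling.

    Keeps every (rate/target_rate)-th sample starting at index 0; the factor
    must be an integer.  Works on Recording or EpochSet.
    """
    factor = obj.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation from {obj.rate} to {target_rate} Hz is not an integer factor"
        )
    factor = int(round(factor))
    if factor == 1:
        return obj.copy()
    sos = sps.butter(order, 0.4 * target_rate, btype="lowpass", fs=obj.rate, output="sos")
    data = _apply_sos(obj.data, sos)[..., ::factor]
    out = replace(obj, data=data, rate=float(target_rate))
    return out


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------


def erp_branch(
    recording: Recording,
    events: EventList,
    *,
    band=(0.1, 30.0),
    window_ms=(-100.0, 1000.0),
    amp_uv: float = 100.0,
    grad_uv: float = 75.0,
    baseline: bool = True,
) -> tuple[EpochSet, RejectionReport]:
    """ERP-average branch: CAR → band-pass → segment → baseline → reject."""
    rec = rereference_average(recording)
    rec = bandpass(rec, *band)
    epochs = epoch(rec, events, *window_ms)
    if baseline:
        epochs = baseline_correct(epochs)
    return reject_artifacts(epochs, amp_uv, grad_uv)


def clf_branch(
    recording: Recording,
    events: EventList,
    keep_event_index=None,
    *,
    window_ms=(0.0, 1000.0),
    target_rate: float = 25.0,
    band=(0.1, 4.0),
) -> EpochSet:
    """Classification branch: segment → zero-mean → decimate → band-pass.

    ``keep_event_index`` (typically the artifact-free events from the ERP
    branch) restricts the trials that enter classification.
    """
    epochs = epoch(recording, events, *window_ms)
    if keep_event_index is not None:
        keep = np.isin(epochs.event_index, np.asarray(keep_event_index, dtype=int))
        epochs = epochs.select_trials(keep)
    epochs = zero_mean(epochs)
    epochs = decimate(epochs, target_rate)
    epochs = bandpass(epochs, *band)
    return epochs
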