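"""Average-ERP branch: subject/grand averages, windowed peaks, behaviour.

Peak amplitudes are taken in two inclusive windows (early 350–600 ms, late
600–850 ms) at the midline parieto-central electrodes; "normalized
amplitudes" follow the vector-scaling reading (each electrode profile
divided by its Euclidean norm).  Group statistics are deliberately not
re-implemented; the tidy tables exported here feed external statistical
software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventList, STIM_CLASSES
from .preprocess import EpochSet

PEAK_WINDOWS_MS = {"early": (350.0, 600.0), "late": (600.0, 850.0)}
PEAK_ELECTRODES = ("CPz", "Pz", "POz")


@dataclass
class ErpAverage:
    """Mean waveform (channels × samples) for one subject/condition/class."""

    data: np.ndarray
    rate: float
    t0_offset_ms: float
    channel_labels: tuple
    n_trials: int
    stim_class: str
    subject: str | None = None
    condition: str | None = None

    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.data.shape[1]) * 1000.0 / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass(frozen=True)
class PeakMeasure:
    """Signed maximum amplitude and its latency within a named window."""

    electrode: str
    window: str
    amplitude_uv: float
    latency_ms: float


def average_erp(
    epochs: EpochSet, stim_class: str, successful_only_index=None
) -> ErpAverage:
    """Arithmetic mean over kept trials of one class.

    For targets, pass the event indices of *successful* targets (answered in
    time) as ``successful_only_index`` so only those enter the average.
    """
    mask = epochs.labels == stim_class
    if successful_only_index is not None:
        mask &= np.isin(epochs.event_index, np.asarray(successful_only_index, int))
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no kept trials of class {stim_class!r}")
    return ErpAverage(
        data=epochs.data[mask].mean(axis=0),
        rate=epochs.rate,
        t0_offset_ms=epochs.t0_offset_ms,
        channel_labels=epochs.channel_labels,
        n_trials=n,
        stim_class=stim_class,
        subject=epochs.subject,
        condition=epochs.condition,
    )


def grand_average(averages: list[ErpAverage]) -> ErpAverage:
    """Unweighted mean of per-subject averages (not trial-weighted)."""
    if not averages:
        raise ValueError("need at least one subject average")
    first = averages[0]
    for a in averages[1:]:
        if a.data.shape != first.data.shape or a.channel_labels != first.channel_labels:
            raise ValueError("subject averages must share channels and time axis")
    return ErpAverage(
        data=np.mean([a.data for a in averages], axis=0),
        rate=first.rate,
        t0_offset_ms=first.t0_offset_ms,
        channel_labels=first.channel_labels,
        n_trials=len(averages),
        stim_class=first.stim_class,
        subject="grand",
        condition=first.condition,
    )


def peak_amplitude(erp: ErpAverage, electrode: str, window) -> PeakMeasure:
    """Maximum signed amplitude in an inclusive window; ties go to the
    earlier latency."""
    if isinstance(window, str):
        name, (lo, hi) = window, PEAK_WINDOWS_MS[window]
    else:
        lo, hi = window
        name = f"{lo:g}-{hi:g}"
    times = erp.times_ms()
    in_win = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not in_win.any():
        raise ValueError(f"window [{lo}, {hi}] ms outside the epoch")
    wave = erp.channel(electrode)[in_win]
    i = int(np.argmax(wave))  # argmax returns the first (earliest) maximum
    return PeakMeasure(
        electrode=electrode,
        window=name,
        amplitude_uv=float(wave[i]),
        latency_ms=float(times[in_win][i]),
    )


def normalize_amplitudes(measures: list[PeakMeasure]) -> list[PeakMeasure]:
    """Vector-scale one electrode profile: divide by its Euclidean norm.

    The input is the set of peak measures across electrodes for one
    subject/condition/class profile; the output profile has unit norm, so a
    uniform amplitude rescaling of the input leaves it unchanged.
    """
    if len(measures) < 2:
        raise ValueError("need at least two electrodes to normalize a profile")
    amps = np.array([m.amplitude_uv for m in measures], dtype=float)
    norm = float(np.linalg.norm(amps))
    if norm == 0:
        raise ValueError("cannot normalize an all-zero amplitude profile")
    return [
        PeakMeasure(m.electrode, m.window, m.amplitude_uv / norm, m.latency_ms)
        for m in measures
    ]


def behavioral_summary(event_lists: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject and per-condition behavioural tables.

    ``event_lists`` maps ``(subject, condition)`` → :class:`EventList` with
    behaviour attached.  Returns ``(per_subject, per_condition)`` frames:
    omission/commission counts and median response time per subject;
    condition totals, mean/SD of per-subject omissions, and the mean of
    per-subject RT medians.
    """
    rows = []
    for (subject, condition), ev in sorted(event_lists.items()):
        is_target = ev.stim_class == "target"
        responded = np.isfinite(ev.response_ms)
        omissions = int(np.sum(is_target & ~responded))
        commissions = int(np.sum(~is_target & responded))
        rts = ev.response_ms[is_target & responded] / 1000.0
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "n_targets": int(is_target.sum()),
                "omissions": omissions,
                "commissions": commissions,
                "rt_median_s": float(np.median(rts)) if rts.size else np.nan,
            }
        )
    per_subject = pd.DataFrame(rows)
    groups = []
    for condition, grp in per_subject.groupby("condition", sort=True):
        groups.append(
            {
                "condition": condition,
                "total_omissions": int(grp["omissions"].sum()),
                "mean_omissions": float(grp["omissions"].mean()),
                "sd_omissions": float(grp["omissions"].std(ddof=1))
                if len(grp) > 1 else np.nan,
                "total_commissions": int(grp["commissions"].sum()),
                "mean_rt_median_s": float(grp["rt_median_s"].mean()),
            }
        )
    return per_subject, pd.DataFrame(groups)


def averages_to_frame(averages: list[ErpAverage]) -> pd.DataFrame:
    """Long-format export: subject, condition, class, channel, time_ms, amplitude_uv."""
    parts = []
    for a in averages:
        times = a.times_ms()
        for ci, ch in enumerate(a.channel_labels):
            parts.append(
                pd.DataFrame(
                    {
                        "subject": a.subject,
                        "condition": a.condition,
                        "class": a.stim_class,
                        "channel": ch,
                        "time_ms": times,
                        "amplitude_uv": a.data[ci],
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def peaks_to_frame(records: list[dict]) -> pd.DataFrame:
    """Tidy peak table from dicts carrying subject/condition/class + PeakMeasure."""
    rows = []
    for rec in records:
        m: PeakMeasure = rec["measure"]
        rows.append(
            {
                "subject": rec.get("subject"),
                "condition": rec.get("condition"),
                "class": rec.get("stim_class"),
                "electrode": m.electrode,
                "window": m.window,
                "amplitude_uv": m.amplitude_uv,
                "latency_ms": m.latency_ms,
            }
        )
    return pd.DataFrame(rows)
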