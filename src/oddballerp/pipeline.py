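"""End-to-end orchestration: generator → branches → pooled evaluation.

The study design pools trials across subjects per task condition (merging
the 13 per-subject datasets into one simple-task and one dual-task set), so
the central object here is the pooled classification-branch
:class:`~oddballerp.preprocess.EpochSet` per condition, built subject by
subject to keep memory bounded.  Trials enter classification only if they
are artifact-free (by the ERP-branch rejection rule) *and* behaviourally
correct (targets answered in 200–2000 ms, non-targets without a response).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as clf
from . import erp as erp_mod
from .io import EventList, Recording, select_channels
from .preprocess import (EpochSet, clf_branch, erp_branch,
                         mark_successful_targets)
from .synth import CONDITIONS, GeneratorConfig, iter_dataset
from .xdawn import fit_xdawn_epochs

PAIR_NAMES = {
    "t/st": ("target", "standard"),
    "d/st": ("deviant", "standard"),
    "t/d": ("target", "deviant"),
}


def behavior_valid_mask(events: EventList) -> np.ndarray:
    """Trials with correct behaviour: successful targets, silent non-targets."""
    is_target = events.stim_class == "target"
    return np.where(is_target, events.successful, ~events.commission)


def subject_clf_epochs(
    recording: Recording,
    events: EventList,
    *,
    amp_uv: float = 100.0,
    grad_uv: float = 75.0,
    rt_window_ms=(200.0, 2000.0),
) -> tuple[EpochSet, "pd.DataFrame"]:
    """Classification-branch epochs for one recording.

    Runs the ERP branch first to obtain artifact decisions, marks successful
    targets, and keeps only artifact-free, behaviourally correct trials.
    Returns the 25 Hz epochs and the rejection-report frame.
    """
    events = mark_successful_targets(events, *rt_window_ms)
    _, report = erp_branch(recording, events, amp_uv=amp_uv, grad_uv=grad_uv)
    valid = behavior_valid_mask(events)
    keep_idx = np.asarray(
        [i for i in report.kept_event_index if valid[i]], dtype=int
    )
    epochs = clf_branch(recording, events, keep_idx)
    return epochs, report.frame


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Pool epoch sets (same channels/rate/window) across subjects."""
    first = parts[0]
    for p in parts[1:]:
        if (p.channel_labels != first.channel_labels or p.rate != first.rate
                or p.n_samples != first.n_samples):
            raise ValueError("epoch sets to pool must share channels, rate, window")
    return EpochSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        rate=first.rate,
        t0_offset_ms=first.t0_offset_ms,
        channel_labels=first.channel_labels,
        labels=np.concatenate([p.labels for p in parts]),
        event_index=np.arange(sum(p.n_trials for p in parts)),
        subject="pooled",
        condition=first.condition,
    )


def pooled_condition_epochs(
    config: GeneratorConfig, condition: str, **preproc_kwargs
) -> EpochSet:
    """Generate, preprocess, and pool all subjects of one condition."""
    parts = []
    for _, _, recording, events in iter_dataset(config, (condition,)):
        epochs, _ = subject_clf_epochs(recording, events, **preproc_kwargs)
        parts.append(epochs)
    return concat_epochs(parts)


def run_detection(
    epochs: EpochSet,
    pair_name: str,
    electrode_set: str,
    window: str,
    *,
    n_repetitions: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> clf.EvalResult:
    """One cell of the no-transfer result tables."""
    sub = select_channels(epochs, electrode_set)
    pair = PAIR_NAMES[pair_name] if pair_name != "multiclass" else None
    return clf.crossvalidate(
        sub,
        pair=pair,
        window=window,
        n_components=clf.N_COMPONENTS[electrode_set],
        n_repetitions=n_repetitions,
        n_folds=n_folds,
        seed=seed,
        config={"condition": epochs.condition, "electrodes": electrode_set},
    )


def run_transfer(
    train_epochs: EpochSet,
    test_epochs: EpochSet,
    pair_name: str,
    electrode_set: str,
    window: str,
    *,
    seed: int = 0,
) -> clf.EvalResult:
    """One cell of the transfer tables (source condition → other condition)."""
    return clf.transfer_evaluate(
        select_channels(train_epochs, electrode_set),
        select_channels(test_epochs, electrode_set),
        pair=PAIR_NAMES[pair_name],
        window=window,
        n_components=clf.N_COMPONENTS[electrode_set],
        seed=seed,
        config={"electrodes": electrode_set},
    )


def classification_table(results: list[clf.EvalResult]) -> pd.DataFrame:
    """Tidy table of evaluation results (machine twin of the result tables)."""
    return pd.DataFrame([r.summary_row() for r in results])


def erp_analysis(
    config: GeneratorConfig,
    conditions=CONDITIONS,
    electrodes=erp_mod.PEAK_ELECTRODES,
    windows=("early", "late"),
):
    """Average-ERP branch over the full synthetic study.

    Returns (grand_averages, peak_table, per_subject_behaviour,
    per_condition_behaviour); grand_averages maps
    (condition, class) → :class:`~oddballerp.erp.ErpAverage`.
    """
    subject_averages: dict = {}
    behavior_events: dict = {}
    peak_records = []
    for subject, condition, recording, events in iter_dataset(config, conditions):
        events = mark_successful_targets(events)
        behavior_events[(subject, condition)] = events
        kept, _ = erp_branch(recording, events)
        successful_idx = np.flatnonzero(events.successful)
        for cls in ("standard", "target", "deviant"):
            avg = erp_mod.average_erp(
                kept, cls,
                successful_only_index=successful_idx if cls == "target" else None,
            )
            subject_averages.setdefault((condition, cls), []).append(avg)
            for electrode in electrodes:
                for window in windows:
                    peak_records.append(
                        {
                            "subject": subject,
                            "condition": condition,
                            "stim_class": cls,
                            "measure": erp_mod.peak_amplitude(avg, electrode, window),
                        }
                    )
    grand = {
        key: erp_mod.grand_average(avgs) for key, avgs in subject_averages.items()
    }
    peaks = erp_mod.peaks_to_frame(peak_records)
    per_subject, per_condition = erp_mod.behavioral_summary(behavior_events)
    return grand, peaks, per_subject, per_condition


def fit_condition_filter(
    epochs: EpochSet, pair_name: str, electrode_set: str
):
    """Spatial filter fitted on the full pooled set of one pair (for maps)."""
    pair = PAIR_NAMES[pair_name]
    sub = select_channels(epochs, electrode_set)
    mask = np.isin(sub.labels, list(pair))
    return fit_xdawn_epochs(
        sub.select_trials(mask),
        clf.EVOKED_CLASS[pair],
        clf.N_COMPONENTS[electrode_set],
        fitted_on={"pair": pair_name, "electrodes": electrode_set,
                   "condition": epochs.condition},
    )
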