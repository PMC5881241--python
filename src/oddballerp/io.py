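"""Data model and I/O for continuous EEG, event tables, and montages.

The in-memory containers used across the package live here:

* :class:`Recording` — continuous multichannel signal in µV,
* :class:`EventList` — ordered stimulus/response events,
* :class:`Montage` — schematic 2-D head layout with named electrode subsets.

Readers/writers cover the BrainVision triplet (``.vhdr``/``.vmrk``/``.eeg``,
multiplexed and vectorized orientations, IEEE float32 and int16 encodings)
and a plain TSV event table.  Internal storage unit is µV throughout; event
onsets are stored in milliseconds so they are independent of sampling rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

STIM_CLASSES = ("standard", "target", "deviant")

#: Electrode subsets used for feature extraction: the full cap, six parietal
#: electrodes around the P3b maximum, and the two midline parietal electrodes.
SUBSETS = {
    "parietal6": ("CPz", "CP3", "CP4", "Pz", "P3", "P4"),
    "parietal2": ("CPz", "Pz"),
}


class FormatError(ValueError):
    """Malformed file content (bad header key, orientation, class token...)."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

# Schematic extended 10-20 rows, front (positive y) to back.  These are 2-D
# head-projection positions adequate for pattern maps; they are not digitised
# electrode coordinates.  FCz is carried in the table (it is the acquisition
# reference and reappears after average re-referencing) but excluded from the
# 62-channel recording set.
_MONTAGE_ROWS = [
    (0.85, ("Fp1", "Fpz", "Fp2")),
    (0.68, ("AF7", "AF3", "AFz", "AF4", "AF8")),
    (0.48, ("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8")),
    (0.25, ("FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8")),
    (0.00, ("T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8")),
    (-0.25, ("TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10")),
    (-0.50, ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8")),
    (-0.70, ("PO7", "PO3", "POz", "PO4", "PO8")),
    (-0.87, ("O1", "Oz", "O2")),
]

REFERENCE_LABEL = "FCz"


def _build_positions() -> dict[str, tuple[float, float]]:
    pos: dict[str, tuple[float, float]] = {}
    for y, labels in _MONTAGE_ROWS:
        half_width = 0.92 * np.sqrt(max(1.0 - y * y, 0.05))
        xs = np.linspace(-half_width, half_width, len(labels)) if len(labels) > 1 else [0.0]
        for label, x in zip(labels, xs):
            pos[label] = (float(x), float(y))
    return pos


@dataclass(frozen=True)
class Montage:
    """2-D head-projection coordinates plus named electrode subsets."""

    positions: dict[str, tuple[float, float]]
    subsets: dict[str, tuple[str, ...]]

    def subset(self, name: str) -> tuple[str, ...]:
        if name not in self.subsets:
            raise KeyError(f"unknown electrode subset {name!r}; known: {sorted(self.subsets)}")
        return self.subsets[name]

    def coords(self, labels) -> np.ndarray:
        missing = [c for c in labels if c not in self.positions]
        if missing:
            raise KeyError(f"montage has no position for: {missing}")
        return np.array([self.positions[c] for c in labels], dtype=float)


def standard_montage() -> Montage:
    """Return the built-in 62-channel extended 10-20 montage (FCz reference)."""
    positions = _build_positions()
    all62 = tuple(
        lab for _, row in _MONTAGE_ROWS for lab in row if lab != REFERENCE_LABEL
    )
    assert len(all62) == 62
    subsets = {"all62": all62, "std62": all62, **SUBSETS}
    return Montage(positions=positions, subsets=subsets)


def montage_channels(name: str) -> tuple[str, ...]:
    """Channel labels for a named montage/subset (std62, parietal6, parietal2)."""
    return standard_montage().subset(name)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        Channels × samples array in µV.
    rate
        Sampling rate in Hz.
    channel_labels
        One label per row of ``data``.
    reference_label
        The (implicit) recording reference; ``"FCz"`` at acquisition,
        ``"average"`` after common-average re-referencing.
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    reference_label: str = REFERENCE_LABEL

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be channels × samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass
class EventList:
    """Ordered stimulus/response events.

    ``response_ms`` is the response latency relative to stimulus onset
    (NaN where no response occurred).  Flags:

    * ``omission`` — target without a response,
    * ``commission`` — response to a non-target,
    * ``successful`` — target answered inside the accepted latency window
      (set by :func:`oddballerp.preprocess.mark_successful_targets`).
    """

    onset_ms: np.ndarray
    stim_class: np.ndarray
    response_ms: np.ndarray
    omission: np.ndarray = None
    commission: np.ndarray = None
    successful: np.ndarray = None
    subject: str | None = None
    condition: str | None = None

    def __post_init__(self):
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.stim_class = np.asarray(self.stim_class, dtype=object)
        self.response_ms = np.asarray(self.response_ms, dtype=float)
        n = len(self.onset_ms)
        unknown = set(self.stim_class) - set(STIM_CLASSES)
        if unknown:
            raise FormatError(f"unknown stimulus class token(s): {sorted(unknown)}")
        for name in ("omission", "commission", "successful"):
            val = getattr(self, name)
            if val is None:
                val = np.zeros(n, dtype=bool)
            setattr(self, name, np.asarray(val, dtype=bool))
        if not (len(self.stim_class) == len(self.response_ms) == n):
            raise ValueError("event columns must have equal length")
        if np.any(np.diff(self.onset_ms) < 0):
            warnings.warn("event onsets were not sorted; sorting", stacklevel=2)
            order = np.argsort(self.onset_ms, kind="stable")
            for name in ("onset_ms", "stim_class", "response_ms",
                         "omission", "commission", "successful"):
                setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return len(self.onset_ms)

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.stim_class == c)) for c in STIM_CLASSES}

    def select(self, mask) -> "EventList":
        mask = np.asarray(mask)
        return EventList(
            onset_ms=self.onset_ms[mask],
            stim_class=self.stim_class[mask],
            response_ms=self.response_ms[mask],
            omission=self.omission[mask],
            commission=self.commission[mask],
            successful=self.successful[mask],
            subject=self.subject,
            condition=self.condition,
        )

    def copy(self) -> "EventList":
        return self.select(np.ones(len(self), dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": self.onset_ms,
                "class": self.stim_class,
                "response_ms": self.response_ms,
                "subject": self.subject if self.subject is not None else "NA",
                "condition": self.condition if self.condition is not None else "NA",
            }
        )


# ---------------------------------------------------------------------------
# Event table TSV
# ---------------------------------------------------------------------------


def write_events(events: EventList, path) -> None:
    """Write an event table as TSV (onset_ms, class, response_ms, subject, condition)."""
    frame = events.to_frame()
    frame["response_ms"] = [
        "NA" if not np.isfinite(v) else f"{v:.6g}" for v in events.response_ms
    ]
    frame.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventList:
    """Read a TSV event table; onsets are sorted on read (with a warning if needed)."""
    frame = pd.read_csv(path, sep="\t", dtype={"class": str}, na_values=["NA"])
    required = {"onset_ms", "class", "response_ms"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"event table missing column(s): {sorted(missing)}")
    stim = frame["class"].to_numpy(dtype=object)
    response = frame["response_ms"].to_numpy(dtype=float)
    subject = condition = None
    if "subject" in frame.columns and len(frame):
        val = str(frame["subject"].iloc[0])
        subject = None if val in ("NA", "nan") else val
    if "condition" in frame.columns and len(frame):
        val = str(frame["condition"].iloc[0])
        condition = None if val in ("NA", "nan") else val
    events = EventList(
        onset_ms=frame["onset_ms"].to_numpy(dtype=float),
        stim_class=stim,
        response_ms=response,
        subject=subject,
        condition=condition,
    )
    events.omission = (events.stim_class == "target") & ~np.isfinite(events.response_ms)
    events.commission = (events.stim_class != "target") & np.isfinite(events.response_ms)
    return events


# ---------------------------------------------------------------------------
# BrainVision triplet
# ---------------------------------------------------------------------------

_BINARY_DTYPES = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}
_ORIENTATIONS = ("MULTIPLEXED", "VECTORIZED")


def write_brainvision(
    recording: Recording,
    header_path,
    *,
    binary_format: str = "IEEE_FLOAT_32",
    orientation: str = "MULTIPLEXED",
    resolution: float = 1.0,
) -> Path:
    """Write a Recording as a BrainVision ``.vhdr``/``.vmrk``/``.eeg`` triplet.

    ``resolution`` is the µV value of one raw unit (honoured for INT_16;
    IEEE float is written with resolution 1, i.e. exact µV).
    """
    header_path = Path(header_path)
    if header_path.suffix != ".vhdr":
        header_path = header_path.with_suffix(".vhdr")
    if binary_format not in _BINARY_DTYPES:
        raise FormatError(f"unsupported BinaryFormat {binary_format!r}")
    if orientation not in _ORIENTATIONS:
        raise FormatError(f"unsupported DataOrientation {orientation!r}")
    stem = header_path.stem
    data_path = header_path.with_suffix(".eeg")
    marker_path = header_path.with_suffix(".vmrk")

    if binary_format == "IEEE_FLOAT_32":
        resolution = 1.0
        raw = recording.data.astype("<f4")
    else:
        raw = np.round(recording.data / resolution)
        info = np.iinfo(np.int16)
        raw = np.clip(raw, info.min, info.max).astype("<i2")
    if orientation == "MULTIPLEXED":
        raw = np.ascontiguousarray(raw.T)  # sample-major interleaving
    raw.tofile(data_path)

    interval_us = 1e6 / recording.rate
    interval_str = (
        f"{interval_us:.0f}" if abs(interval_us - round(interval_us)) < 1e-9
        else f"{interval_us!r}"
    )
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by oddballerp",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval_str}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={label},{recording.reference_label},{resolution:g},µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    marker_lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    marker_path.write_text("\n".join(marker_lines) + "\n", encoding="utf-8")
    return header_path


def _parse_vhdr(text: str) -> dict:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, _, value = line.partition("=")
            sections[current][key.strip()] = value.strip()
    return sections


def read_brainvision(header_path) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording` (data in µV)."""
    header_path = Path(header_path)
    sections = _parse_vhdr(header_path.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    chinfo = sections.get("Channel Infos", {})

    for key in ("DataFile", "NumberOfChannels", "SamplingInterval"):
        if key not in common:
            raise FormatError(f"header missing required key {key!r}")
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation not in _ORIENTATIONS:
        raise FormatError(f"unsupported DataOrientation {orientation!r}")
    binary_format = binary.get("BinaryFormat", "IEEE_FLOAT_32").upper()
    if binary_format not in _BINARY_DTYPES:
        raise FormatError(f"unsupported BinaryFormat {binary_format!r}")

    n_channels = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])

    labels, references, resolutions = [], [], []
    for i in range(1, n_channels + 1):
        key = f"Ch{i}"
        if key not in chinfo:
            raise FormatError(f"header missing channel entry {key!r}")
        parts = chinfo[key].split(",")
        labels.append(parts[0])
        references.append(parts[1] if len(parts) > 1 and parts[1] else REFERENCE_LABEL)
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    data_path = header_path.parent / common["DataFile"]
    if not data_path.exists():
        raise FormatError(f"data file referenced by DataFile not found: {data_path}")
    raw = np.fromfile(data_path, dtype=_BINARY_DTYPES[binary_format])
    if raw.size % n_channels:
        raise FormatError("data file size is not a multiple of NumberOfChannels")
    n_samples = raw.size // n_channels
    if orientation == "MULTIPLEXED":
        data = raw.reshape(n_samples, n_channels).T.astype(float)
    else:
        data = raw.reshape(n_channels, n_samples).astype(float)
    data = data * np.asarray(resolutions, dtype=float)[:, None]
    return Recording(
        data=data,
        rate=rate,
        channel_labels=tuple(labels),
        reference_label=references[0],
    )


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------


def select_channels(obj, subset):
    """Restrict a Recording or EpochSet to a named subset or explicit label list.

    Output channel order follows the subset definition order.  Idempotent and
    composable: all62 → parietal6 → parietal2 equals all62 → parietal2.
    """
    if isinstance(subset, str):
        labels = montage_channels(subset)
    else:
        labels = tuple(subset)
    have = {lab: i for i, lab in enumerate(obj.channel_labels)}
    missing = [lab for lab in labels if lab not in have]
    if missing:
        raise KeyError(f"channel(s) not present: {missing}")
    idx = [have[lab] for lab in labels]
    if obj.data.ndim == 2:  # Recording: channels × samples
        data = obj.data[idx]
    else:  # EpochSet: trials × channels × samples
        data = obj.data[:, idx]
    return replace(obj, data=data, channel_labels=labels)
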