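"""Domain types, dataset manifest I/O, and window segmentation.

A *dataset* is a collection of labelled recordings from one or more
body-worn sensor units, each unit housing one or more tri-axial sensors
(accelerometer, gyroscope, magnetometer, or a derived channel such as
gravity-removed body acceleration).  Every tri-axial sensor contributes a
3xN sample block, rows being the x, y, z axes and columns the time
samples.  Recordings are cut into fixed-length windows (*segments*), the
atomic unit of transformation, feature extraction and classification.

On disk a dataset is a YAML manifest plus one delimited-text channel file
per (recording, unit, sensor): one row per time sample, three columns per
tri-axial sensor in axis order x, y, z.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import yaml
from scipy import signal as _signal

SENSOR_TYPES = ("accelerometer", "gyroscope", "magnetometer", "derived")

CASES = ("reference", "random_rotation", "euclidean_norm", "heuristic", "svd")


class DatasetFormatError(ValueError):
    """Raised when a manifest or channel file violates the on-disk format.

    The message always names the offending file and, where meaningful,
    the 1-based line number.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SensorChannelSet:
    """One tri-axial sensor's 3xN sample block.

    Parameters
    ----------
    unit_id : str
        Identifier of the physical sensor unit (all sensors in a unit
        share one orientation on the body).
    sensor_type : str
        One of ``SENSOR_TYPES``.
    samples : ndarray, shape (3, N)
        Rows are the x, y, z axes; columns are time samples.
    rate : float
        Sampling rate in Hz.
    """

    unit_id: str
    sensor_type: str
    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValueError(
                f"samples must be 3xN, got shape {self.samples.shape}"
            )
        if self.samples.shape[1] < 1:
            raise ValueError("samples must contain at least one column")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sensor_type not in SENSOR_TYPES:
            raise ValueError(f"unknown sensor type {self.sensor_type!r}")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class Recording:
    """All channel blocks of one continuous single-activity recording."""

    subject_id: str
    activity_id: str
    channels: List[SensorChannelSet]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a recording needs at least one channel block")
        n0, r0 = self.channels[0].n_samples, self.channels[0].rate
        seen = set()
        for ch in self.channels:
            if ch.n_samples != n0 or ch.rate != r0:
                raise ValueError(
                    "all channel blocks of a recording must share N and rate"
                )
            key = (ch.unit_id, ch.sensor_type)
            if key in seen:
                raise ValueError(f"duplicate channel block for {key}")
            seen.add(key)

    @property
    def n_samples(self) -> int:
        return self.channels[0].n_samples

    @property
    def rate(self) -> float:
        return self.channels[0].rate

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Segment:
    """A fixed-length labelled window of all channel blocks of a recording.

    ``blocks`` maps ``(unit_id, sensor_type)`` to a 3xL array; insertion
    order is the canonical channel order of the dataset.
    """

    subject_id: str
    activity_id: str
    blocks: Dict[Tuple[str, str], np.ndarray]
    length: int
    rate: float
    segment_index: int

    def __post_init__(self) -> None:
        for key, block in self.blocks.items():
            if block.shape != (3, self.length):
                raise ValueError(
                    f"block {key} has shape {block.shape}, "
                    f"expected (3, {self.length})"
                )


@dataclass
class DatasetMetadata:
    """Units, per-unit sensor lists, rate, and the label catalogs."""

    units: List[str]
    sensors_per_unit: Dict[str, List[str]]
    rate: float
    activities: List[str]
    subjects: List[str]
    window_s: float = 5.0
    overlap_fraction: float = 0.0

    def channel_keys(self) -> List[Tuple[str, str]]:
        """Canonical (unit, sensor) order: manifest unit order, then the
        declared sensor order within each unit."""
        return [
            (u, s) for u in self.units for s in self.sensors_per_unit[u]
        ]


@dataclass
class Dataset:
    recordings: List[Recording]
    metadata: DatasetMetadata

    def __post_init__(self) -> None:
        keys = set(self.metadata.channel_keys())
        for rec in self.recordings:
            rec_keys = {(c.unit_id, c.sensor_type) for c in rec.channels}
            if rec_keys != keys:
                raise ValueError(
                    f"recording ({rec.subject_id}, {rec.activity_id}) channels "
                    f"{sorted(rec_keys)} do not match metadata {sorted(keys)}"
                )
            if rec.rate != self.metadata.rate:
                raise ValueError("recording rate does not match metadata")


@dataclass
class PipelineConfig:
    """Knobs of the evaluation pipeline.

    ``case`` selects the experimental condition: the untouched reference,
    per-segment random rotation (simulating arbitrary mounting), the
    per-sample Euclidean norm, the 9-channel heuristic transform
    (optionally truncated to its first 3 or 6 channels), or the SVD-based
    transform.  ``pca_dims`` is the retained dimensionality after PCA
    (30 by default).  ``pca_fit_mode`` / ``scale_fit_mode`` choose whether
    PCA directions and the per-sensor-type variance scales are fitted on
    the training folds only (leakage-free) or on all data (the pooled
    convention this pipeline mirrors).
    """

    window_s: float = 5.0
    overlap_fraction: float = 0.0
    case: str = "reference"
    heuristic_elements: int = 9
    pca_dims: int = 30
    pca_fit_mode: str = "train_only"
    scale_fit_mode: str = "train_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(
                f"unknown case {self.case!r}; allowed: {', '.join(CASES)}"
            )
        if self.heuristic_elements not in (3, 6, 9):
            raise ValueError("heuristic_elements must be 3, 6 or 9")
        if self.pca_dims < 1:
            raise ValueError("pca_dims must be >= 1")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.pca_fit_mode not in ("train_only", "all_data"):
            raise ValueError("pca_fit_mode must be 'train_only' or 'all_data'")
        if self.scale_fit_mode not in ("train_only", "all_data"):
            raise ValueError("scale_fit_mode must be 'train_only' or 'all_data'")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def window_length(window_s: float, rate: float) -> int:
    """Number of samples per window, ``round(window_s * rate)``."""
    return int(round(window_s * rate))


def segment_recording(
    recording: Recording, window_s: float, overlap_fraction: float = 0.0
) -> List[Segment]:
    """Cut a recording into fixed-length windows.

    Windows start at multiples of ``hop = round(L * (1 - overlap_fraction))``
    samples; a trailing stretch shorter than one window is discarded.  A
    recording shorter than one window yields an empty list.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    L = window_length(window_s, recording.rate)
    if L < 1:
        raise ValueError(f"window of {window_s} s is empty at rate {recording.rate} Hz")
    hop = int(round(L * (1 - overlap_fraction)))
    hop = max(hop, 1)
    N = recording.n_samples
    segments: List[Segment] = []
    start = 0
    index = 0
    while start + L <= N:
        blocks = {
            (ch.unit_id, ch.sensor_type): ch.samples[:, start : start + L].copy()
            for ch in recording.channels
        }
        segments.append(
            Segment(
                subject_id=recording.subject_id,
                activity_id=recording.activity_id,
                blocks=blocks,
                length=L,
                rate=recording.rate,
                segment_index=index,
            )
        )
        start += hop
        index += 1
    return segments


def segment_dataset(
    dataset: Dataset, window_s: float, overlap_fraction: float = 0.0
) -> List[Segment]:
    """Segment every recording, preserving recording order; the per-dataset
    segment index is made unique by renumbering consecutively."""
    out: List[Segment] = []
    for rec in dataset.recordings:
        out.extend(segment_recording(rec, window_s, overlap_fraction))
    for i, seg in enumerate(out):
        seg.segment_index = i
    return out


# ---------------------------------------------------------------------------
# Gravity removal (derived channel)
# ---------------------------------------------------------------------------

def gravity_highpass(
    block: np.ndarray, rate: float, cutoff: float = 0.3
) -> np.ndarray:
    """Remove the quasi-static (gravity) component of an acceleration block.

    A zero-phase forward-backward 2nd-order Butterworth high-pass is run
    along each axis.  This is a conventional body/gravity separation used
    to build a derived body-acceleration channel; it is not claimed to
    match any particular dataset provider's filter.
    """
    block = np.asarray(block, dtype=float)
    if not 0 < cutoff < rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, rate/2) = (0, {rate / 2}), got {cutoff}"
        )
    sos = _signal.butter(2, cutoff, btype="highpass", fs=rate, output="sos")
    return _signal.sosfiltfilt(sos, block, axis=1)


# ---------------------------------------------------------------------------
# Manifest reader / writer
# ---------------------------------------------------------------------------

def _channel_file_key(unit: str, sensor: str) -> str:
    return f"{unit}/{sensor}"


def write_dataset(dataset: Dataset, out_dir) -> Path:
    """Write a dataset as a YAML manifest plus CSV channel files.

    Returns the manifest path.  Channel files hold one row per time
    sample, three comma-separated columns (x, y, z), no header.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    md = dataset.metadata
    rec_entries = []
    for i, rec in enumerate(dataset.recordings):
        files = {}
        for ch in rec.channels:
            fname = f"rec{i:04d}_{rec.subject_id}_{rec.activity_id}_{ch.unit_id}_{ch.sensor_type}.csv"
            np.savetxt(out_dir / fname, ch.samples.T, delimiter=",", fmt="%.17g")
            files[_channel_file_key(ch.unit_id, ch.sensor_type)] = fname
        rec_entries.append(
            {"subject": rec.subject_id, "activity": rec.activity_id, "files": files}
        )
    manifest = {
        "rate": float(md.rate),
        "window_s": float(md.window_s),
        "overlap_fraction": float(md.overlap_fraction),
        "delimiter": ",",
        "header": False,
        "units": [
            {"id": u, "sensors": list(md.sensors_per_unit[u])} for u in md.units
        ],
        "activities": list(md.activities),
        "subjects": list(md.subjects),
        "recordings": rec_entries,
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def _read_channel_file(
    path: Path, delimiter: str, header: bool
) -> np.ndarray:
    rows: List[List[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise DatasetFormatError(
                    f"{path}:{lineno}: expected 3 columns, found {len(row)}"
                )
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                raise DatasetFormatError(
                    f"{path}:{lineno}: non-numeric cell in row {row!r}"
                ) from None
    if not rows:
        raise DatasetFormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float).T  # -> 3xN


def read_dataset(manifest_path) -> Dataset:
    """Read a dataset from a YAML manifest (see `write_dataset`)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    rate = float(manifest["rate"])
    if rate <= 0:
        raise DatasetFormatError(f"{manifest_path}: rate must be positive, got {rate}")
    delimiter = manifest.get("delimiter", ",")
    header = bool(manifest.get("header", False))
    units = [u["id"] for u in manifest["units"]]
    sensors_per_unit = {u["id"]: list(u["sensors"]) for u in manifest["units"]}
    for u, sensors in sensors_per_unit.items():
        for s in sensors:
            if s not in SENSOR_TYPES:
                raise DatasetFormatError(
                    f"{manifest_path}: unknown sensor type {s!r} in unit {u!r}"
                )
    md = DatasetMetadata(
        units=units,
        sensors_per_unit=sensors_per_unit,
        rate=rate,
        activities=list(manifest.get("activities", [])),
        subjects=list(manifest.get("subjects", [])),
        window_s=float(manifest.get("window_s", 5.0)),
        overlap_fraction=float(manifest.get("overlap_fraction", 0.0)),
    )
    recordings = []
    for entry in manifest["recordings"]:
        channels = []
        for unit in units:
            for sensor in sensors_per_unit[unit]:
                key = _channel_file_key(unit, sensor)
                if key not in entry["files"]:
                    raise DatasetFormatError(
                        f"{manifest_path}: recording ({entry['subject']}, "
                        f"{entry['activity']}) lists no file for "
                        f"(unit={unit!r}, sensor={sensor!r})"
                    )
                fpath = base / entry["files"][key]
                if not fpath.exists():
                    raise DatasetFormatError(
                        f"{manifest_path}: missing channel file {fpath} for "
                        f"(unit={unit!r}, sensor={sensor!r})"
                    )
                samples = _read_channel_file(fpath, delimiter, header)
                channels.append(
                    SensorChannelSet(
                        unit_id=unit, sensor_type=sensor, samples=samples, rate=rate
                    )
                )
        recordings.append(
            Recording(
                subject_id=str(entry["subject"]),
                activity_id=str(entry["activity"]),
                channels=channels,
            )
        )
    return Dataset(recordings=recordings, metadata=md)
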