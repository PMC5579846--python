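"""Experiment harness: five cases, two cross-validation schemes.

The five experimental conditions are

* ``reference`` -- raw sensor axes, fixed mounting;
* ``random_rotation`` -- every (segment, unit) pair is rotated by an
  independent random proper rotation before feature extraction,
  simulating sensors worn at arbitrary orientations;
* ``euclidean_norm`` -- per-sample Euclidean norm of each tri-axial
  block (one channel per sensor);
* ``heuristic`` -- the 9-channel heuristic transform (or its first 3 or
  6 channels);
* ``svd`` -- the per-unit joint SVD transform.

Accuracy is estimated by P-fold cross-validation (random, non-stratified
partition into P nearly equal parts, P = 10 by default) and by
leave-one-subject-out (one fold per subject), the latter probing
inter-subject generalization.

Per-subject [0, 1] normalization uses each subject's own min/max and is
applied before the train/test split; this mirrors the pooled convention
of the evaluation protocol this module reproduces and leaks each
subject's range into training.  PCA directions and the SVD sensor
scales are fitted per fold on training data by default, with an
``all_data`` pooled mode available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classifiers as _clf
from .core import Dataset, PipelineConfig, Segment, segment_dataset
from .features import (
    FeatureSpec,
    LABEL_COLUMNS,
    build_feature_table,
    feature_columns,
    normalize_per_subject,
    pca_reduce,
)
from .heuristic import (
    HEURISTIC_CHANNEL_NAMES,
    euclidean_norm_transform,
    heuristic_transform,
    truncate_channels,
)
from .rotation import random_rotation, rotate_segment
from .svd import SensorScales, fit_sensor_scales_from_segments, svd_transform

__all__ = [
    "CVResult",
    "pfold_partition",
    "l1o_partition",
    "segment_channels",
    "make_feature_table",
    "run_case",
    "summarize",
]

AXIS_NAMES = ("x", "y", "z")


@dataclass
class CVResult:
    """Per-fold accuracies and the pooled confusion matrix of one
    (case, classifier, scheme) experiment."""

    scheme: str
    case: str
    classifier: str
    fold_accuracies: List[float]
    confusion: pd.DataFrame  # K x K counts, rows = true class
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        """Sample standard deviation over folds (0 for a single fold)."""
        if len(self.fold_accuracies) < 2:
            return 0.0
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "case": self.case,
            "classifier": self.classifier,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion": {
                "classes": [str(c) for c in self.confusion.index],
                "counts": self.confusion.to_numpy().tolist(),
            },
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Cross-validation partitions
# ---------------------------------------------------------------------------

def pfold_partition(
    n_rows: int, P: int, seed: int | np.random.Generator
) -> List[np.ndarray]:
    """Random disjoint exhaustive partition of row indices into P parts
    whose sizes differ by at most one (not stratified)."""
    if P > n_rows:
        raise ValueError(f"P={P} exceeds the number of rows {n_rows}")
    if P < 2:
        raise ValueError("P must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm = rng.permutation(n_rows)
    return [np.sort(part) for part in np.array_split(perm, P)]


def l1o_partition(subjects: Sequence) -> List[np.ndarray]:
    """One fold per subject, holding all and only that subject's rows."""
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [np.flatnonzero(subjects == s) for s in uniq]


# ---------------------------------------------------------------------------
# Case-specific channel construction
# ---------------------------------------------------------------------------

def segment_channels(
    segment: Segment,
    case: str = "reference",
    heuristic_elements: int = 9,
    scales: Optional[SensorScales] = None,
) -> Dict[str, np.ndarray]:
    """Named 1-D channels of one segment under the given case.

    Channel order is the segment's block order (the dataset's canonical
    unit/sensor order), with per-block rows in transform row order.
    """
    out: Dict[str, np.ndarray] = {}
    if case in ("reference", "random_rotation"):
        for (unit, sensor), block in segment.blocks.items():
            for i, ax in enumerate(AXIS_NAMES):
                out[f"{unit}:{sensor}:{ax}"] = block[i]
    elif case == "euclidean_norm":
        for (unit, sensor), block in segment.blocks.items():
            out[f"{unit}:{sensor}:norm"] = euclidean_norm_transform(block)[0]
    elif case == "heuristic":
        for (unit, sensor), block in segment.blocks.items():
            ch = truncate_channels(heuristic_transform(block), heuristic_elements)
            for i in range(ch.shape[0]):
                out[f"{unit}:{sensor}:{HEURISTIC_CHANNEL_NAMES[i]}"] = ch[i]
    elif case == "svd":
        if scales is None:
            raise ValueError("the svd case requires fitted SensorScales")
        by_unit: Dict[str, List[Tuple[str, np.ndarray]]] = {}
        for (unit, sensor), block in segment.blocks.items():
            by_unit.setdefault(unit, []).append((sensor, block))
        for unit, pairs in by_unit.items():
            sensors = [s for s, _ in pairs]
            blocks = [b for _, b in pairs]
            transformed = svd_transform(blocks, sensors, scales)
            for sensor, tblock in zip(sensors, transformed):
                for i in range(3):
                    out[f"{unit}:{sensor}:p{i + 1}"] = tblock[i]
    else:
        raise ValueError(f"unknown case {case!r}")
    return out


def _inject_rotations(
    segments: Sequence[Segment], seed: int | np.random.Generator
) -> Tuple[List[Segment], List[Tuple[int, str, np.ndarray]]]:
    """Rotate every (segment, unit) pair by a fresh random rotation.

    Returns the rotated segments and a log of (segment position, unit,
    matrix); applying the transposes of the logged matrices restores the
    input.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rotated: List[Segment] = []
    log: List[Tuple[int, str, np.ndarray]] = []
    for pos, seg in enumerate(segments):
        units = list(dict.fromkeys(u for (u, _) in seg.blocks))
        rots = {}
        for u in units:
            r = random_rotation(rng)
            rots[u] = r
            log.append((pos, u, r))
        rotated.append(rotate_segment(seg, rots))
    return rotated, log


def make_feature_table(
    dataset: Dataset,
    config: PipelineConfig,
    spec: FeatureSpec = FeatureSpec(),
    inject_rotation_seed: Optional[int] = None,
    scales: Optional[SensorScales] = None,
) -> pd.DataFrame:
    """Segment a dataset, apply the configured case, and extract features.

    ``inject_rotation_seed`` additionally rotates every (segment, unit)
    pair before the case transform -- used to probe end-to-end
    orientation invariance of the OIT cases.  For the svd case,
    ``scales`` defaults to a fit over all segments of this dataset
    (before any injected rotation, since the scales are corpus constants
    of the method, not of the mounting).
    """
    segments = segment_dataset(dataset, config.window_s, config.overlap_fraction)
    if config.case == "svd" and scales is None:
        scales = fit_sensor_scales_from_segments(segments)
    if config.case == "random_rotation":
        segments, _ = _inject_rotations(segments, config.seed)
    if inject_rotation_seed is not None:
        segments, _ = _inject_rotations(segments, inject_rotation_seed)
    pairs = [
        (
            (seg.subject_id, seg.activity_id, seg.segment_index),
            segment_channels(seg, config.case, config.heuristic_elements, scales),
        )
        for seg in segments
    ]
    return build_feature_table(pairs, spec, rate=dataset.metadata.rate)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

def _accuracy_and_confusion(
    true: np.ndarray, pred: np.ndarray, classes: Sequence
) -> Tuple[float, np.ndarray]:
    acc = float(np.mean(true == pred))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(true, pred):
        conf[index[t], index[p]] += 1
    return acc, conf


def run_case(
    dataset: Dataset,
    config: PipelineConfig,
    classifier: str = "knn",
    scheme: str = "pfold",
    P: int = 10,
    clf_config: Optional[_clf.ClassifierConfig] = None,
    spec: FeatureSpec = FeatureSpec(),
) -> CVResult:
    """Run one (case, classifier, CV scheme) experiment end to end.

    Per fold: case transform -> feature extraction -> per-subject
    normalization -> PCA to ``config.pca_dims`` -> train/test.  The
    returned accuracy is the fraction of correctly labelled test
    segments; the confusion matrix pools all folds.
    """
    if scheme not in ("pfold", "l1o"):
        raise ValueError("scheme must be 'pfold' or 'l1o'")
    if clf_config is None:
        clf_config = _clf.ClassifierConfig(seed=config.seed)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rot_rng = np.random.default_rng(seeds[0])
    part_rng = np.random.default_rng(seeds[1])

    segments = segment_dataset(dataset, config.window_s, config.overlap_fraction)
    if config.case == "random_rotation":
        segments, _ = _inject_rotations(segments, rot_rng)
    rate = dataset.metadata.rate

    def table_with_scales(scales: Optional[SensorScales]) -> pd.DataFrame:
        pairs = [
            (
                (seg.subject_id, seg.activity_id, seg.segment_index),
                segment_channels(
                    seg, config.case, config.heuristic_elements, scales
                ),
            )
            for seg in segments
        ]
        return normalize_per_subject(build_feature_table(pairs, spec, rate=rate))

    per_fold_scales = config.case == "svd" and config.scale_fit_mode == "train_only"
    table = None
    if not per_fold_scales:
        scales = (
            fit_sensor_scales_from_segments(segments)
            if config.case == "svd"
            else None
        )
        table = table_with_scales(scales)

    subjects = np.asarray([seg.subject_id for seg in segments])
    n = len(segments)
    if scheme == "pfold":
        folds = pfold_partition(n, P, part_rng)
    else:
        folds = l1o_partition(subjects)

    classes = sorted({seg.activity_id for seg in segments})
    conf_total = np.zeros((len(classes), len(classes)), dtype=int)
    accuracies: List[float] = []
    for test_idx in folds:
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        if per_fold_scales:
            fold_scales = fit_sensor_scales_from_segments(
                [segments[i] for i in np.flatnonzero(~mask)]
            )
            fold_table = table_with_scales(fold_scales)
        else:
            fold_table = table
        train = fold_table.loc[~mask]
        test = fold_table.loc[mask]
        train_p, test_p, _ = pca_reduce(
            train, test, M=config.pca_dims, fit_mode=config.pca_fit_mode
        )
        cols = feature_columns(train_p)
        pred = _clf.fit_predict(
            classifier,
            train_p[cols].to_numpy(),
            train_p["activity"].to_numpy(),
            test_p[cols].to_numpy(),
            clf_config,
        )
        acc, conf = _accuracy_and_confusion(
            test_p["activity"].to_numpy(), pred, classes
        )
        accuracies.append(acc)
        conf_total += conf

    return CVResult(
        scheme=scheme,
        case=config.case,
        classifier=classifier,
        fold_accuracies=accuracies,
        confusion=pd.DataFrame(conf_total, index=classes, columns=classes),
        seed=config.seed,
    )


def summarize(results: Iterable[CVResult]) -> pd.DataFrame:
    """Tabulate mean accuracy with a +-2 std band per (case, classifier,
    scheme), and each case's accuracy difference from the reference case
    under the same classifier and scheme (NaN when no reference run is
    present)."""
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    ref: Dict[Tuple[str, str], float] = {}
    for r in results:
        if r.case == "reference":
            ref[(r.classifier, r.scheme)] = r.mean_accuracy
    for r in results:
        base = ref.get((r.classifier, r.scheme))
        rows.append(
            {
                "case": r.case,
                "classifier": r.classifier,
                "scheme": r.scheme,
                "mean_accuracy": r.mean_accuracy,
                "band_low": r.mean_accuracy - 2 * r.std_accuracy,
                "band_high": r.mean_accuracy + 2 * r.std_accuracy,
                "delta_vs_reference": (
                    r.mean_accuracy - base if base is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
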