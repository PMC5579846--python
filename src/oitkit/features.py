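"""Per-channel feature extraction, per-subject normalization, and PCA.

From every channel of a (possibly transformed) segment the following
features are taken, in fixed order:

* min, max, mean, skewness, kurtosis (population moments; kurtosis is
  non-excess; zero-variance channels yield 0 for both shape moments);
* the biased autocorrelation a(l) at lag 0 (the variance) and at every
  fifth lag up to 50, keeping only lags <= L-1;
* the five largest one-sided DFT magnitude peaks and their frequencies
  in Hz, peaks being at least 11 bins apart, zero-filled when fewer
  admissible peaks exist.

This yields 5 + (1 + #surviving lags) + 2*5 features per channel -- 26
for a 125-sample window, 23 for a 40-sample window -- concatenated over
channels in the dataset's canonical channel order.

Feature tables are plain pandas DataFrames with label columns
``subject``, ``activity``, ``segment_index`` followed by the feature
columns.  Features are then min-max scaled to [0, 1] per subject, and
PCA reduces the table to its first M principal dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

LABEL_COLUMNS = ("subject", "activity", "segment_index")

__all__ = [
    "LABEL_COLUMNS",
    "FeatureSpec",
    "autocorr_lag_set",
    "autocorrelation",
    "dft_peaks",
    "channel_feature_count",
    "extract_features",
    "build_feature_table",
    "feature_columns",
    "split_labels",
    "normalize_per_subject",
    "pca_reduce",
    "scree",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Which features are extracted from each channel."""

    base_stats: Tuple[str, ...] = ("min", "max", "mean", "skewness", "kurtosis")
    autocorr_step: int = 5
    autocorr_max_lag: int = 50
    n_dft_peaks: int = 5
    dft_min_separation: int = 11

    def __post_init__(self) -> None:
        if self.n_dft_peaks < 1 or self.dft_min_separation < 1:
            raise ValueError("n_dft_peaks and dft_min_separation must be >= 1")


def autocorr_lag_set(L: int, spec: FeatureSpec = FeatureSpec()) -> List[int]:
    """Lag 0 plus every ``step``-th lag up to ``max_lag``, truncated to
    lags representable in a length-L window (lag <= L-1)."""
    lags = [0]
    lags += [
        l
        for l in range(spec.autocorr_step, spec.autocorr_max_lag + 1, spec.autocorr_step)
        if l <= L - 1
    ]
    return lags


def autocorrelation(x: np.ndarray, lags: Sequence[int]) -> np.ndarray:
    """Biased, mean-removed autocorrelation:

        a(l) = (1/L) * sum_{n=0}^{L-1-l} (x[n]-mean)(x[n+l]-mean)

    so a(0) is exactly the population variance.
    """
    x = np.asarray(x, dtype=float)
    L = x.size
    c = x - x.mean()
    out = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if not 0 <= lag < L:
            raise ValueError(f"lag {lag} out of range for length {L}")
        out[i] = np.dot(c[: L - lag], c[lag:]) / L
    return out


def dft_peaks(
    x: np.ndarray,
    n_peaks: int = 5,
    min_separation: int = 11,
    rate: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Largest one-sided DFT magnitude peaks and their frequencies.

    The magnitude spectrum is evaluated on bins 0..floor(L/2).  Peaks are
    picked greedily, largest first (lowest bin wins ties), subject to a
    pairwise bin distance of at least ``min_separation``.  Frequencies
    are ``bin * rate / L`` in Hz.  If fewer than ``n_peaks`` admissible
    peaks exist, the remaining magnitude/frequency slots are zero so the
    output width is fixed.
    """
    x = np.asarray(x, dtype=float)
    L = x.size
    if L < 1:
        raise ValueError("empty sequence")
    mag = np.abs(np.fft.rfft(x))
    order = np.argsort(-mag, kind="stable")
    chosen: List[int] = []
    for b in order:
        if mag[b] == 0.0:  # a flat zero bin is not a peak
            break
        if all(abs(int(b) - c) >= min_separation for c in chosen):
            chosen.append(int(b))
            if len(chosen) == n_peaks:
                break
    mags = np.zeros(n_peaks)
    freqs = np.zeros(n_peaks)
    for i, b in enumerate(chosen):
        mags[i] = mag[b]
        freqs[i] = b * rate / L
    return mags, freqs


def channel_feature_count(L: int, spec: FeatureSpec = FeatureSpec()) -> int:
    """Features per channel for a length-L window."""
    return len(spec.base_stats) + len(autocorr_lag_set(L, spec)) + 2 * spec.n_dft_peaks


def _shape_moments(x: np.ndarray) -> Tuple[float, float]:
    # population skewness and (non-excess) kurtosis; 0 on zero variance
    c = x - x.mean()
    m2 = np.mean(c**2)
    if m2 <= 0:
        return 0.0, 0.0
    m3 = np.mean(c**3)
    m4 = np.mean(c**4)
    return float(m3 / m2**1.5), float(m4 / m2**2)


def extract_features(
    channels: Mapping[str, np.ndarray],
    spec: FeatureSpec = FeatureSpec(),
    rate: float = 1.0,
) -> "pd.Series":
    """Feature vector of one segment: per-channel features concatenated
    in the mapping's iteration order, with unique descriptive names."""
    if not channels:
        raise ValueError("no channels supplied")
    names: List[str] = []
    values: List[float] = []
    lengths = {len(np.asarray(v).ravel()) for v in channels.values()}
    if len(lengths) != 1:
        raise ValueError(f"channels have unequal lengths {sorted(lengths)}")
    (L,) = lengths
    if L < 2:
        raise ValueError("channels must contain at least 2 samples")
    for ch_name, x in channels.items():
        x = np.asarray(x, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite input in channel {ch_name!r}")
        skew, kurt = _shape_moments(x)
        base = {
            "min": float(x.min()),
            "max": float(x.max()),
            "mean": float(x.mean()),
            "skewness": skew,
            "kurtosis": kurt,
        }
        for stat in spec.base_stats:
            names.append(f"{ch_name}:{stat}")
            values.append(base[stat])
        lags = autocorr_lag_set(L, spec)
        ac = autocorrelation(x, lags)
        for lag, a in zip(lags, ac):
            names.append(f"{ch_name}:ac{lag}")
            values.append(float(a))
        mags, freqs = dft_peaks(x, spec.n_dft_peaks, spec.dft_min_separation, rate)
        for i in range(spec.n_dft_peaks):
            names.append(f"{ch_name}:dftmag{i + 1}")
            values.append(float(mags[i]))
        for i in range(spec.n_dft_peaks):
            names.append(f"{ch_name}:dftfreq{i + 1}")
            values.append(float(freqs[i]))
    return pd.Series(values, index=names)


def build_feature_table(
    segment_channels: Sequence[Tuple[Tuple[str, str, int], Mapping[str, np.ndarray]]],
    spec: FeatureSpec = FeatureSpec(),
    rate: float = 1.0,
) -> pd.DataFrame:
    """Assemble a feature table from (labels, channels) pairs, where the
    labels are (subject, activity, segment_index)."""
    rows = []
    labels = []
    for (subject, activity, index), channels in segment_channels:
        rows.append(extract_features(channels, spec, rate))
        labels.append((subject, activity, index))
    feats = pd.DataFrame(rows).reset_index(drop=True)
    lab = pd.DataFrame(labels, columns=list(LABEL_COLUMNS))
    return pd.concat([lab, feats], axis=1)


def feature_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c not in LABEL_COLUMNS]


def split_labels(table: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """(feature matrix, activity labels, subject labels) of a table."""
    cols = feature_columns(table)
    return (
        table[cols],
        table["activity"].to_numpy(),
        table["subject"].to_numpy(),
    )


def normalize_per_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale every feature column to [0, 1] independently for
    each subject; a column constant within a subject maps to 0."""
    if table.empty:
        raise ValueError("empty feature table")
    out = table.copy()
    cols = feature_columns(table)
    for _, idx in table.groupby("subject", sort=False).groups.items():
        block = out.loc[idx, cols]
        lo = block.min(axis=0)
        hi = block.max(axis=0)
        span = hi - lo
        span[span == 0] = np.inf  # constant columns -> 0
        out.loc[idx, cols] = (block - lo) / span
    return out


def _fit_pca(x: np.ndarray, n_components: int) -> PCA:
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    return pca


def pca_reduce(
    train: pd.DataFrame,
    test: pd.DataFrame,
    M: int = 30,
    fit_mode: str = "train_only",
) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Project both tables onto the first M principal directions.

    Directions are fitted on the training table alone
    (``fit_mode='train_only'``) or on the concatenation of both
    (``'all_data'``, the pooled convention).  Returns the projected
    train and test tables (feature columns ``pc1..pcM``) and the fitted
    eigenvalues in non-increasing order.
    """
    cols = feature_columns(train)
    if M > len(cols):
        raise ValueError(f"M={M} exceeds feature count {len(cols)}")
    if fit_mode == "train_only":
        fit_x = train[cols].to_numpy()
    elif fit_mode == "all_data":
        fit_x = np.vstack([train[cols].to_numpy(), test[cols].to_numpy()])
    else:
        raise ValueError("fit_mode must be 'train_only' or 'all_data'")
    pca = _fit_pca(fit_x, M)
    pc_cols = [f"pc{i + 1}" for i in range(M)]

    def _project(tbl: pd.DataFrame) -> pd.DataFrame:
        proj = pd.DataFrame(
            pca.transform(tbl[cols].to_numpy()), columns=pc_cols,
            index=tbl.index,
        )
        return pd.concat([tbl[list(LABEL_COLUMNS)], proj], axis=1)

    return _project(train), _project(test), pca.explained_variance_.copy()


def scree(table: pd.DataFrame, n: int | None = None) -> np.ndarray:
    """First ``n`` eigenvalues of the feature covariance matrix, in
    non-increasing order (all of them when ``n`` is None)."""
    cols = feature_columns(table)
    x = table[cols].to_numpy()
    pca = _fit_pca(x, min(x.shape[0] - 1 if x.shape[0] > 1 else 1, len(cols)))
    ev = pca.explained_variance_
    return ev[:n] if n is not None else ev
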