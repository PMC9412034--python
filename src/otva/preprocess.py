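"""QRS delineation, normalization/alignment and bin-mean downsampling.

The classification inputs are max-abs-normalized QRS windows centered on the
R peak, and their 10-bin mean representation ("raw10"): each lead's window is
split into contiguous near-equal bins and replaced by the per-bin mean
potential, which acts as a compact pseudo-feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic_ecg import LEAD_NAMES, Dataset, ECGRecord, SOOLabel
from .transforms import wavelet_transform

__all__ = [
    "QRSSegment",
    "DownsampledBeat",
    "delineate_qrs",
    "normalize_and_align",
    "downsample_bins",
    "BeatPreprocessor",
    "raw10_matrix",
]

# Delineation thresholds, relative to the window's maximum scale-2 modulus.
PEAK_THRESHOLD = 0.25
SUB_THRESHOLD = 0.03


@dataclass
class QRSSegment:
    """Normalized, R-centered QRS window (12 leads x L samples)."""

    signal: np.ndarray
    fs: float
    r_index: int
    source_record_id: str | None = None
    qrs_duration_ms: float | None = None
    label: SOOLabel | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(LEAD_NAMES):
            raise ValueError("segment must be 12 leads x L samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def lead(self, name: str) -> np.ndarray:
        return self.signal[LEAD_NAMES.index(name)]


@dataclass
class DownsampledBeat:
    """Bin-mean representation of a segment: 12 leads x n_bins values."""

    values: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Lead-major concatenation (I bins, II bins, ..., V6 bins)."""
        return self.values.ravel()


def delineate_qrs(record) -> tuple[int, int]:
    """Detect the QRS window from scale-2 wavelet modulus maxima.

    The per-lead scale-2 moduli are combined by a max across leads; the QRS
    onset is the last sub-threshold sample before the first supra-threshold
    modulus maximum, the offset the first sub-threshold sample after the
    last, with thresholds relative to the window's maximum modulus.
    Returns a half-open ``(onset, offset)`` window.
    """
    signal = np.asarray(record.signal, dtype=float)
    if not np.any(signal):
        raise ValueError("no QRS found: flat (all-zero) signal")
    modulus = np.zeros(signal.shape[1])
    for lead in signal:
        w2 = wavelet_transform(lead, scales=(2,)).scale(2)
        np.maximum(modulus, np.abs(w2), out=modulus)
    m = modulus.max()
    if m <= 0:
        raise ValueError("no QRS found: zero wavelet modulus")
    above = np.flatnonzero(modulus >= PEAK_THRESHOLD * m)
    first, last = int(above[0]), int(above[-1])
    sub = modulus < SUB_THRESHOLD * m
    before = np.flatnonzero(sub[: first + 1])
    onset = int(before[-1]) if len(before) else 0
    after = np.flatnonzero(sub[last:])
    offset = last + int(after[0]) if len(after) else signal.shape[1]
    return onset, offset


def normalize_and_align(
    record,
    onset: int,
    offset: int,
    window_ms: float = 200.0,
    per_lead: bool = False,
) -> QRSSegment:
    """Baseline-correct, max-abs normalize and center a QRS on its R peak.

    The per-lead baseline (mean of the 10 ms preceding the onset) is
    subtracted, samples outside ``[onset, offset)`` are zeroed, the window is
    divided by its global (across-lead) max-abs — or per-lead when
    ``per_lead`` — and re-centered on the R peak in a fixed-length window of
    ``window_ms``, zero-padded where the record does not cover it.
    """
    signal = np.asarray(record.signal, dtype=float)
    fs = record.fs
    T = signal.shape[1]
    if not 0 <= onset < offset <= T:
        raise ValueError(f"invalid QRS window [{onset}, {offset}) for T={T}")

    pre = round(10.0 * fs / 1000.0)
    lo = max(0, onset - pre)
    baseline = (signal[:, lo:onset].mean(axis=1) if onset > lo
                else np.zeros(signal.shape[0]))
    corrected = signal - baseline[:, None]

    windowed = np.zeros_like(corrected)
    windowed[:, onset:offset] = corrected[:, onset:offset]

    if per_lead:
        denom = np.max(np.abs(windowed), axis=1, keepdims=True)
        if np.any(denom == 0):
            raise ValueError("degenerate signal: a lead has zero max-abs")
    else:
        denom = np.max(np.abs(windowed))
        if denom == 0:
            raise ValueError("degenerate signal: window max-abs is zero")
    normalized = windowed / denom

    L = round(window_ms * fs / 1000.0)
    center = L // 2
    r = int(record.r_peak)
    out = np.zeros((signal.shape[0], L))
    src_lo = max(0, r - center)
    src_hi = min(T, r - center + L)
    dst_lo = src_lo - (r - center)
    out[:, dst_lo:dst_lo + (src_hi - src_lo)] = normalized[:, src_lo:src_hi]

    return QRSSegment(
        signal=out,
        fs=fs,
        r_index=center,
        source_record_id=getattr(record, "record_id", None),
        qrs_duration_ms=(offset - onset) * 1000.0 / fs,
        label=getattr(record, "label", None),
        weight=float(getattr(record, "sample_weight", 1.0)),
    )


def downsample_bins(segment: QRSSegment, n_bins: int = 10) -> DownsampledBeat:
    """Per-lead bin means over contiguous near-equal bins.

    When ``L`` is not divisible by ``n_bins`` the remainder samples are
    assigned to the leading bins (deterministic tie-break).
    """
    x = segment.signal
    L = x.shape[1]
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if L < n_bins:
        raise ValueError(f"segment length {L} shorter than n_bins={n_bins}")
    base, rem = divmod(L, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    sums = np.add.reduceat(x, edges[:-1], axis=1)
    values = sums / sizes
    return DownsampledBeat(values=values, bin_edges=edges)


class BeatPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: beats -> QRS segments or raw10 rows.

    Parameters
    ----------
    window_ms : fixed analysis window length centered on the R peak.
    n_bins : number of bin means per lead in the raw10 output.
    use_true_fiducials : use the generator's ground-truth QRS bounds when a
        record carries them; otherwise (or when False) delineate with the
        wavelet detector.
    per_lead : normalize each lead independently instead of globally.
    output : ``"segments"`` (list of QRSSegment) or ``"raw10"``
        (array of shape ``(n_beats, 12 * n_bins)``).
    """

    def __init__(self, window_ms: float = 200.0, n_bins: int = 10,
                 use_true_fiducials: bool = True, per_lead: bool = False,
                 output: str = "segments"):
        self.window_ms = window_ms
        self.n_bins = n_bins
        self.use_true_fiducials = use_true_fiducials
        self.per_lead = per_lead
        self.output = output

    def fit(self, X, y=None):
        if self.output not in ("segments", "raw10"):
            raise ValueError("output must be 'segments' or 'raw10'")
        self.is_fitted_ = True
        return self

    def transform(self, X):
        records = X.records if isinstance(X, Dataset) else list(X)
        segments = []
        for rec in records:
            if self.use_true_fiducials and getattr(rec, "qrs_onset", None) is not None:
                onset, offset = rec.qrs_onset, rec.qrs_offset
            else:
                onset, offset = delineate_qrs(rec)
            segments.append(normalize_and_align(
                rec, onset, offset,
                window_ms=self.window_ms, per_lead=self.per_lead))
        if self.output == "segments":
            return segments
        return np.vstack([
            downsample_bins(s, self.n_bins).flatten() for s in segments
        ])

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.array([
            f"raw.{lead}.bin{b}" for lead in LEAD_NAMES
            for b in range(self.n_bins)
        ])


def raw10_matrix(dataset, n_bins: int = 10, window_ms: float = 200.0,
                 use_true_fiducials: bool = True):
    """Convenience: dataset -> (X raw10 matrix, chamber labels, weights)."""
    pre = BeatPreprocessor(window_ms=window_ms, n_bins=n_bins,
                           use_true_fiducials=use_true_fiducials,
                           output="raw10")
    X = pre.fit_transform(dataset)
    records = dataset.records if isinstance(dataset, Dataset) else list(dataset)
    y = np.array([r.label.chamber for r in records])
    w = np.array([float(getattr(r, "sample_weight", 1.0)) for r in records])
    return X, y, w
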