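"""QRS feature battery: signal-, wavelet- and spectral-based descriptors.

Three families are computed per beat:

* signal family (161 values): QRS duration and precordial transition code,
  eight morphology descriptors per lead, and three comparative descriptors
  for each of the 21 within-group lead pairs;
* wavelet family (136 values): the same transition code on scale-1 wavelet
  extrema, six per-lead descriptors of the scale-1 coefficients (including
  fragmentation and the R/S amplitude ratio from the detected fiducials) and
  the three comparative descriptors on scale-1 coefficients;
* spectral family (84 values): per-lead fundamental frequency and six
  band-averaged powers of the Welch periodogram over
  [0,3), [3,6), [6,9), [9,12), [12,25) and [25,50) Hz.

The literal enumeration yields 381 named values per beat.  Every vector is
total and NaN-free: absent fiducials are imputed (S amplitude floored at a
machine-epsilon-bounded value), zero-amplitude polarities default to +1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BeatPreprocessor, QRSSegment
from .synthetic_ecg import LEAD_NAMES, Dataset
from .transforms import (
    FiducialSet,
    PowerSpectrum,
    detect_fiducials,
    wavelet_transform,
    welch_psd,
)

__all__ = [
    "LeadPairSet",
    "LEAD_GROUPS",
    "SPECTRAL_BANDS",
    "comparison_pairs",
    "precordial_transition",
    "extract_signal_features",
    "extract_wavelet_features",
    "extract_spectral_features",
    "beat_features",
    "feature_names",
    "extract_feature_matrix",
    "FeatureExtractor",
]

LEAD_GROUPS: dict[str, tuple[str, ...]] = {
    "limb": ("I", "II", "III"),
    "augmented": ("aVR", "aVL", "aVF"),
    "precordial": ("V1", "V2", "V3", "V4", "V5", "V6"),
}

PRECORDIAL = LEAD_GROUPS["precordial"]

SPECTRAL_BANDS: tuple[tuple[float, float], ...] = (
    (0, 3), (3, 6), (6, 9), (9, 12), (12, 25), (25, 50),
)

#: Floor for the S-wave amplitude when the S fiducial is absent.
_S_FLOOR = float(np.sqrt(np.finfo(float).eps))


@dataclass(frozen=True)
class LeadPairSet:
    """Ordered within-group lead pairs used for comparative features."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def comparison_pairs(groups=("limb", "augmented", "precordial")) -> LeadPairSet:
    """All ordered in-group pairs: 3 limb + 3 augmented + 15 precordial."""
    pairs = []
    for g in groups:
        leads = LEAD_GROUPS[g]
        pairs.extend(itertools.combinations(leads, 2))
    return LeadPairSet(pairs=tuple(pairs))


def _signed_maximum(x: np.ndarray) -> float:
    """Value of the sample with the largest magnitude (0 -> +0.0)."""
    return float(x[int(np.argmax(np.abs(x)))])


def _polarity(x: np.ndarray) -> float:
    v = _signed_maximum(x)
    return 1.0 if v >= 0 else -1.0


def _transition_code(signed_maxima: np.ndarray) -> float:
    """First precordial index whose polarity differs from V1's, over 5.

    Zero-amplitude maxima count as positive; if no lead changes polarity the
    sentinel 1.0 (the V6 code) is returned.
    """
    signs = np.where(signed_maxima >= 0, 1.0, -1.0)
    for k in range(1, 6):
        if signs[k] != signs[0]:
            return k / 5.0
    return 1.0


def precordial_transition(segment: QRSSegment) -> float:
    """Transition code in [0, 1] from the signed maxima of V1..V6."""
    sm = np.array([_signed_maximum(segment.lead(v)) for v in PRECORDIAL])
    return _transition_code(sm)


def _xcorr(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag normalized (Pearson-style) cross-correlation in [-1, 1]."""
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = np.linalg.norm(a0) * np.linalg.norm(b0)
    if denom < 1e-30:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.clip(a0 @ b0 / denom, -1.0, 1.0))


def _areas(x: np.ndarray, dt_ms: float) -> tuple[float, float]:
    """Raw (signed) and absolute trapezoidal areas, in amplitude x ms."""
    return (float(np.trapezoid(x, dx=dt_ms)),
            float(np.trapezoid(np.abs(x), dx=dt_ms)))


def extract_signal_features(
    segment: QRSSegment,
    onset: int | None = None,
    offset: int | None = None,
    pairs: LeadPairSet | None = None,
) -> dict[str, float]:
    """Signal-based family: 2 all-lead + 8 x 12 per-lead + 3 x 21 comparative."""
    if pairs is None:
        pairs = comparison_pairs()
    dt_ms = 1000.0 / segment.fs
    if onset is not None and offset is not None:
        duration_ms = (offset - onset) * dt_ms
    elif segment.qrs_duration_ms is not None:
        duration_ms = segment.qrs_duration_ms
    else:
        raise ValueError("QRS onset/offset required for the duration feature")

    out: dict[str, float] = {
        "sig.qrs_duration": float(duration_ms),
        "sig.precordial_transition": precordial_transition(segment),
    }
    for name in LEAD_NAMES:
        x = segment.lead(name)
        vmax, vmin = float(x.max()), float(x.min())
        area, absarea = _areas(x, dt_ms)
        out[f"sig.polarity.{name}"] = _polarity(x)
        out[f"sig.vmax.{name}"] = vmax
        out[f"sig.vmin.{name}"] = vmin
        out[f"sig.absmax_signed.{name}"] = _signed_maximum(x)
        out[f"sig.absmax.{name}"] = float(np.max(np.abs(x)))
        out[f"sig.amplitude.{name}"] = vmax - vmin
        out[f"sig.area.{name}"] = area
        out[f"sig.absarea.{name}"] = absarea
    for a, b in pairs:
        diff = segment.lead(a) - segment.lead(b)
        out[f"sig.diffmax.{a}_{b}"] = _signed_maximum(diff)
        out[f"sig.diffarea.{a}_{b}"] = float(np.trapezoid(diff, dx=dt_ms))
        out[f"sig.xcorr.{a}_{b}"] = _xcorr(segment.lead(a), segment.lead(b))
    return out


def extract_wavelet_features(
    segment: QRSSegment,
    w1: dict[str, np.ndarray],
    fiducials: dict[str, FiducialSet | None],
    pairs: LeadPairSet | None = None,
) -> dict[str, float]:
    """Wavelet-based family on scale-1 coefficients: 1 + 6 x 12 + 3 x 21."""
    if pairs is None:
        pairs = comparison_pairs()
    dt_ms = 1000.0 / segment.fs

    sm = np.array([_signed_maximum(w1[v]) for v in PRECORDIAL])
    out: dict[str, float] = {"wav.precordial_transition": _transition_code(sm)}

    for name in LEAD_NAMES:
        w = w1[name]
        area, absarea = _areas(w, dt_ms)
        frag = area / absarea if absarea > 0 else 0.0
        fid = fiducials.get(name)
        x = segment.lead(name)
        if fid is not None and fid.r_peak is not None:
            r_amp = abs(x[fid.r_peak])
            s_amp = abs(x[fid.s_peak]) if fid.s_peak is not None else 0.0
        else:
            r_amp, s_amp = 0.0, 0.0
        rs_ratio = r_amp / max(s_amp, _S_FLOOR)
        out[f"wav.max.{name}"] = float(w.max())
        out[f"wav.min.{name}"] = float(w.min())
        out[f"wav.mean.{name}"] = float(w.mean())
        out[f"wav.area.{name}"] = area
        out[f"wav.fragmentation.{name}"] = float(frag)
        out[f"wav.rs_ratio.{name}"] = float(rs_ratio)
    for a, b in pairs:
        diff = w1[a] - w1[b]
        out[f"wav.diffarea.{a}_{b}"] = float(np.trapezoid(diff, dx=dt_ms))
        out[f"wav.diffmax.{a}_{b}"] = _signed_maximum(diff)
        out[f"wav.xcorr.{a}_{b}"] = _xcorr(w1[a], w1[b])
    return out


def extract_spectral_features(
    segment: QRSSegment,
    spectra: dict[str, PowerSpectrum],
) -> dict[str, float]:
    """Spectral family: per-lead fundamental frequency + 6 band powers."""
    out: dict[str, float] = {}
    for name in LEAD_NAMES:
        ps = spectra[name]
        if ps.fs / 2.0 < SPECTRAL_BANDS[-1][1]:
            raise ValueError(
                "sampling rate too low: spectral bands up to 50 Hz unresolvable"
            )
        out[f"spec.f0.{name}"] = float(ps.frequencies[int(np.argmax(ps.power))])
        for lo, hi in SPECTRAL_BANDS:
            sel = (ps.frequencies >= lo) & (ps.frequencies < hi)
            band = float(ps.power[sel].mean()) if np.any(sel) else 0.0
            out[f"spec.band_{lo:g}_{hi:g}.{name}"] = band
    return out


def beat_features(
    segment: QRSSegment,
    families=("signal", "wavelet", "spectral"),
    flank_threshold: float = 0.125,
) -> dict[str, float]:
    """Full named feature vector for one preprocessed beat."""
    out: dict[str, float] = {}
    if "signal" in families:
        out.update(extract_signal_features(segment))
    if "wavelet" in families:
        w1: dict[str, np.ndarray] = {}
        fiducials: dict[str, FiducialSet | None] = {}
        for name in LEAD_NAMES:
            x = segment.lead(name)
            decomp = wavelet_transform(x, scales=(1, 2, 3, 4))
            w1[name] = decomp.scale(1)
            try:
                fiducials[name] = detect_fiducials(
                    decomp, segment.r_index, flank_threshold=flank_threshold)
            except ValueError:
                fiducials[name] = None
        out.update(extract_wavelet_features(segment, w1, fiducials))
    if "spectral" in families:
        spectra = {
            name: welch_psd(segment.lead(name), segment.fs)
            for name in LEAD_NAMES
        }
        out.update(extract_spectral_features(segment, spectra))
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite feature values: {bad[:5]}")
    return out


def feature_names(families=("signal", "wavelet", "spectral")) -> list[str]:
    """Canonical column order for a given family selection."""
    pairs = comparison_pairs()
    names: list[str] = []
    if "signal" in families:
        names += ["sig.qrs_duration", "sig.precordial_transition"]
        for lead in LEAD_NAMES:
            names += [f"sig.{f}.{lead}" for f in (
                "polarity", "vmax", "vmin", "absmax_signed", "absmax",
                "amplitude", "area", "absarea")]
        for a, b in pairs:
            names += [f"sig.diffmax.{a}_{b}", f"sig.diffarea.{a}_{b}",
                      f"sig.xcorr.{a}_{b}"]
    if "wavelet" in families:
        names += ["wav.precordial_transition"]
        for lead in LEAD_NAMES:
            names += [f"wav.{f}.{lead}" for f in (
                "max", "min", "mean", "area", "fragmentation", "rs_ratio")]
        for a, b in pairs:
            names += [f"wav.diffarea.{a}_{b}", f"wav.diffmax.{a}_{b}",
                      f"wav.xcorr.{a}_{b}"]
    if "spectral" in families:
        for lead in LEAD_NAMES:
            names += [f"spec.f0.{lead}"]
            names += [f"spec.band_{lo:g}_{hi:g}.{lead}"
                      for lo, hi in SPECTRAL_BANDS]
    return names


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Sklearn transformer: QRS segments -> feature DataFrame (381 columns)."""

    def __init__(self, families=("signal", "wavelet", "spectral"),
                 flank_threshold: float = 0.125):
        self.families = families
        self.flank_threshold = flank_threshold

    def fit(self, X, y=None):
        self.feature_names_ = feature_names(self.families)
        self.is_fitted_ = True
        return self

    def transform(self, X) -> pd.DataFrame:
        names = feature_names(self.families)
        rows = [beat_features(s, families=self.families,
                              flank_threshold=self.flank_threshold)
                for s in X]
        frame = pd.DataFrame(rows, columns=names)
        return frame

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names(self.families))


def extract_feature_matrix(
    data,
    families=("signal", "wavelet", "spectral"),
    window_ms: float = 200.0,
    use_true_fiducials: bool = True,
    with_labels: bool = True,
) -> pd.DataFrame:
    """Feature table for a dataset or a list of segments.

    Rows are beats, columns the canonical feature names; when labels are
    available the table gains ``label_chamber``, ``label_sublocation`` and
    ``sample_weight`` columns.
    """
    if isinstance(data, Dataset) or (
            data and not isinstance(data[0], QRSSegment)):
        pre = BeatPreprocessor(window_ms=window_ms,
                               use_true_fiducials=use_true_fiducials)
        segments = pre.fit_transform(data)
    else:
        segments = list(data)
    fs_set = {s.fs for s in segments}
    if len(fs_set) > 1:
        raise ValueError(f"inconsistent sampling rates across beats: {fs_set}")
    frame = FeatureExtractor(families=families).fit_transform(segments)
    if with_labels:
        frame["label_chamber"] = [
            s.label.chamber if s.label else None for s in segments]
        frame["label_sublocation"] = [
            s.label.sublocation if s.label else None for s in segments]
        frame["sample_weight"] = [s.weight for s in segments]
    return frame
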