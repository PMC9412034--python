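"""Signal transforms: a-trous wavelet bank, fiducial detection, Welch PSD.

The wavelet is the classic quadratic-spline derivative-of-smoothing wavelet
used by multiscale QRS delineators: its coefficients behave like smoothed
derivatives of the input, so monophasic waves map to pairs of
opposite-signed modulus maxima whose zero crossing marks the wave peak.  The
transform is implemented undecimated (algorithme a trous, symmetric boundary
extension) so every scale stays aligned with the signal grid and zero
crossings are comparable across scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "WaveletDecomposition",
    "FiducialSet",
    "PowerSpectrum",
    "wavelet_transform",
    "detect_fiducials",
    "welch_psd",
]

# Quadratic-spline filter bank: lowpass smoothing h, highpass derivative g.
_H = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
_G = np.array([2.0, -2.0])

#: Relative modulus threshold below which flanking (Q/S) lobes are ignored.
DEFAULT_FLANK_THRESHOLD = 0.125


@dataclass
class WaveletDecomposition:
    """Undecimated wavelet coefficients, one full-length vector per scale."""

    coefficients: dict[int, np.ndarray]
    n_samples: int

    def scale(self, s: int) -> np.ndarray:
        return self.coefficients[s]

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(sorted(self.coefficients))


@dataclass
class FiducialSet:
    """Q/R/S peak sample indices for one lead (absent waves are ``None``).

    ``r_polarity`` is +1 for an upright dominant wave, -1 for inverted;
    Q and S, when present, have the opposite polarity of R.
    """

    r_peak: int | None = None
    q_peak: int | None = None
    s_peak: int | None = None
    r_polarity: int = 1

    def __post_init__(self) -> None:
        present = [p for p in (self.q_peak, self.r_peak, self.s_peak)
                   if p is not None]
        if present != sorted(present):
            raise ValueError("fiducials must satisfy q_peak < r_peak < s_peak")


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density estimate."""

    frequencies: np.ndarray
    power: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < -1e-15):
            raise ValueError("spectral power must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly ascending")


def _conv_sym(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Convolve with symmetric boundary extension, output aligned to input."""
    pad = len(filt)
    xp = np.pad(x, pad, mode="symmetric")
    full = np.convolve(xp, filt)
    off = len(filt) // 2
    return full[pad + off: pad + off + len(x)]


def _upsample(filt: np.ndarray, dilation: int) -> np.ndarray:
    if dilation == 1:
        return filt
    up = np.zeros((len(filt) - 1) * dilation + 1)
    up[::dilation] = filt
    return up


def wavelet_transform(x: np.ndarray, scales=(1, 2, 3, 4, 5)) -> WaveletDecomposition:
    """Undecimated quadratic-spline wavelet transform at dyadic scales 1-5."""
    x = np.asarray(x, dtype=float).ravel()
    scales = sorted(set(int(s) for s in scales))
    if not scales or scales[0] < 1 or scales[-1] > 5:
        raise ValueError("scales must be a non-empty subset of {1..5}")
    if len(x) < 2 ** scales[-1]:
        raise ValueError(
            f"signal of length {len(x)} too short for scale {scales[-1]}"
        )
    coeffs: dict[int, np.ndarray] = {}
    approx = x
    for k in range(1, scales[-1] + 1):
        d = 2 ** (k - 1)
        w = _conv_sym(approx, _upsample(_G, d))
        if k in scales:
            coeffs[k] = w
        approx = _conv_sym(approx, _upsample(_H, d))
    return WaveletDecomposition(coefficients=coeffs, n_samples=len(x))


def _local_modulus_maxima(w: np.ndarray, floor: float) -> np.ndarray:
    """Indices of strict local maxima of |w| above ``floor``."""
    m = np.abs(w)
    idx = sps.argrelextrema(m, np.greater_equal, order=1)[0]
    # drop plateau duplicates and sub-floor extrema
    keep = []
    for i in idx:
        if m[i] <= floor:
            continue
        if keep and i == keep[-1] + 1 and m[i] == m[keep[-1]]:
            continue
        keep.append(int(i))
    return np.array(keep, dtype=int)


def _zero_crossing(w: np.ndarray, lo: int, hi: int) -> int:
    """Sample index of the sign change of ``w`` inside [lo, hi]."""
    seg = w[lo:hi + 1]
    signs = np.sign(seg)
    for i in range(len(seg) - 1):
        if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]:
            # nearest sample to the interpolated crossing
            frac = abs(seg[i]) / (abs(seg[i]) + abs(seg[i + 1]))
            return lo + i + int(round(frac))
        if signs[i + 1] == 0:
            return lo + i + 1
    return lo + int(np.argmin(np.abs(seg)))


def detect_fiducials(
    decomp: WaveletDecomposition,
    r_hint: int,
    flank_threshold: float = DEFAULT_FLANK_THRESHOLD,
) -> FiducialSet:
    """Locate Q/R/S peaks from opposite-signed modulus-maxima pairs.

    The dominant pair is found at scale 4 near ``r_hint``, propagated down to
    scale 1, and the R peak is the zero crossing between the refined pair.
    Flanking pairs whose modulus exceeds ``flank_threshold`` times the
    maximum scale-1 modulus contribute the Q and S peaks; monophasic waves
    report them absent.
    """
    for s in (1, 2, 3, 4):
        if s not in decomp.coefficients:
            raise ValueError("detect_fiducials requires wavelet scales 1-4")

    w4 = decomp.scale(4)
    floor4 = 0.05 * np.max(np.abs(w4)) if np.max(np.abs(w4)) > 0 else 0.0
    maxima4 = _local_modulus_maxima(w4, floor4)
    pairs = [
        (maxima4[i], maxima4[i + 1])
        for i in range(len(maxima4) - 1)
        if np.sign(w4[maxima4[i]]) != np.sign(w4[maxima4[i + 1]])
    ]
    if not pairs:
        raise ValueError("no QRS morphology: no opposite-signed modulus-maxima pair")

    def pair_score(p):
        n1, n2 = p
        strength = min(abs(w4[n1]), abs(w4[n2]))
        dist = abs(0.5 * (n1 + n2) - r_hint)
        return strength / (1.0 + dist / max(decomp.n_samples, 1))

    n1, n2 = max(pairs, key=pair_score)

    # Propagate the pair down the scales, refining each extremum locally.
    for s in (3, 2, 1):
        w = decomp.scale(s)
        win = 2 ** (s + 1)
        n1 = _refine_extremum(w, n1, win, np.sign(decomp.scale(s + 1)[n1]))
        n2 = _refine_extremum(w, n2, win, np.sign(decomp.scale(s + 1)[n2]))
    w1 = decomp.scale(1)
    if n1 >= n2:
        n1, n2 = min(n1, n2), max(n1, n2)
        if n1 == n2:
            raise ValueError("no QRS morphology: degenerate modulus-maxima pair")
    r_peak = _zero_crossing(w1, n1, n2)
    r_polarity = 1 if w1[n1] > 0 else -1

    max1 = np.max(np.abs(w1))
    thr = flank_threshold * max1
    maxima1 = _local_modulus_maxima(w1, 0.0)

    q_peak = s_peak = None
    before = [i for i in maxima1 if i < n1 - 1
              and np.sign(w1[i]) == -np.sign(w1[n1]) and abs(w1[i]) >= thr]
    if before:
        a = before[-1]
        q_peak = _zero_crossing(w1, a, n1)
        if not q_peak < r_peak:
            q_peak = None
    after = [i for i in maxima1 if i > n2 + 1
             and np.sign(w1[i]) == -np.sign(w1[n2]) and abs(w1[i]) >= thr]
    if after:
        b = after[0]
        s_peak = _zero_crossing(w1, n2, b)
        if not s_peak > r_peak:
            s_peak = None

    return FiducialSet(r_peak=r_peak, q_peak=q_peak, s_peak=s_peak,
                       r_polarity=r_polarity)


def _refine_extremum(w: np.ndarray, idx: int, win: int, sign: float) -> int:
    """Nearest same-signed modulus maximum of ``w`` within ``idx +- win``."""
    lo = max(0, idx - win)
    hi = min(len(w), idx + win + 1)
    seg = w[lo:hi]
    if sign == 0:
        sign = 1.0
    cand = seg * sign  # look for the largest same-signed excursion
    j = int(np.argmax(cand))
    if cand[j] <= 0:
        j = int(np.argmax(np.abs(seg)))
    return lo + j


def welch_psd(x: np.ndarray, fs: float, nfft: int = 256) -> PowerSpectrum:
    """Welch averaged periodogram (Hann taper, 50% overlap).

    Segment length is ``min(256, L)``; short signals are zero-padded to
    ``nfft`` bins so the low-frequency band features stay resolvable.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 16:
        raise ValueError("welch_psd requires at least 16 samples")
    nperseg = min(256, len(x))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=max(nfft, nperseg),
        detrend=False,
    )
    return PowerSpectrum(frequencies=freqs, power=np.maximum(power, 0.0), fs=fs)
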