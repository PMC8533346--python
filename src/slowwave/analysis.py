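"""LFP synthesis and analysis: amplitude distributions, Up/Down segmentation,
Welch spectrograms in dB and high/low band ratios.

The LFP of a population is the sum of the absolute AMPAergic and GABAergic
synaptic currents; the pyramidal LFP is the headline signal.  During NREM its
pooled distribution is bimodal (Up/Down alternation) and the half distance
between the two smoothed modes serves as the Up/Down threshold; during wake
the distribution is unimodal and no threshold exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage, signal

#: default Gaussian smoothing width (mV) of the LFP histogram per population
SMOOTH_C = {"p": 55.0, "i": 5.0}
DEFAULT_BIN_MV = 0.5


def compute_lfp(i_ampa: np.ndarray, i_gaba: np.ndarray) -> np.ndarray:
    """``LFP = |I_AMPA| + |I_GABA|`` (elementwise)."""
    return np.abs(i_ampa) + np.abs(i_gaba)


def demean_prestimulus(x: np.ndarray, pre: slice) -> np.ndarray:
    """Subtract each trial's prestimulus temporal mean from the whole trial."""
    x = np.asarray(x)
    if pre.stop is not None and pre.stop > x.shape[-1]:
        raise ValueError("prestimulus window extends past the trial")
    return x - x[..., pre].mean(axis=-1, keepdims=True)


@dataclass
class LabeledDistribution:
    """Histogram normalized by the total event count across all labels."""

    edges: np.ndarray
    probs: np.ndarray
    label: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def mode(self) -> float:
        return float(self.centers[int(np.argmax(self.probs))])

    @property
    def mass(self) -> float:
        return float(self.probs.sum())


def histogram(samples: np.ndarray, bin_width: float = DEFAULT_BIN_MV,
              lo: Optional[float] = None, hi: Optional[float] = None
              ) -> LabeledDistribution:
    """Fixed-bin-width histogram normalized to unit mass."""
    x = np.asarray(samples, float).ravel()
    lo = np.floor(x.min() / bin_width) * bin_width if lo is None else lo
    hi = np.ceil(x.max() / bin_width) * bin_width if hi is None else hi
    hi = max(hi, lo + bin_width)
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return LabeledDistribution(edges, counts / max(x.size, 1))


@dataclass
class UpDownResult:
    """Outcome of the bimodality search on the smoothed LFP distribution."""

    bimodal: bool
    threshold: Optional[float] = None   # mV, midpoint of the two modes
    peaks: Tuple[float, ...] = ()       # mode locations, ascending
    smoothed: Optional[np.ndarray] = None
    edges: Optional[np.ndarray] = None


def updown_threshold(dist: LabeledDistribution, c: float = SMOOTH_C["p"],
                     min_rel_height: float = 1e-3) -> UpDownResult:
    """Locate the Up and Down modes of an LFP distribution.

    The histogram is smoothed with a Gaussian kernel of width ``c`` (mV on the
    support axis); the two largest interior maxima separated by a local
    minimum define the modes and the threshold is their midpoint.  A unimodal
    distribution yields an explicit no-bimodality result (the wake regime).
    """
    bin_width = float(dist.edges[1] - dist.edges[0])
    smoothed = ndimage.gaussian_filter1d(dist.probs.astype(float),
                                         sigma=c / bin_width, mode="constant")
    pk, _ = signal.find_peaks(smoothed,
                              height=min_rel_height * smoothed.max())
    centers = dist.centers
    if pk.size < 2:
        return UpDownResult(False, smoothed=smoothed, edges=dist.edges)
    # two largest maxima; ties broken toward larger separation
    order = np.argsort(smoothed[pk])[::-1]
    top = sorted(pk[order[:2]])
    interior = smoothed[top[0]:top[1] + 1]
    if interior.min() >= min(smoothed[top[0]], smoothed[top[1]]):
        return UpDownResult(False, smoothed=smoothed, edges=dist.edges)
    lo, hi = centers[top[0]], centers[top[1]]
    return UpDownResult(True, threshold=0.5 * (lo + hi), peaks=(lo, hi),
                        smoothed=smoothed, edges=dist.edges)


def updown_labels(lfp: np.ndarray, c: float = SMOOTH_C["p"],
                  bin_width: float = DEFAULT_BIN_MV
                  ) -> Tuple[UpDownResult, Optional[np.ndarray]]:
    """Threshold the pooled LFP and label every sample Up (True)/Down."""
    dist = histogram(lfp, bin_width)
    res = updown_threshold(dist, c)
    if not res.bimodal:
        return res, None
    return res, np.asarray(lfp) > res.threshold


def split_distributions(series: np.ndarray, labels: np.ndarray,
                        bin_width: float) -> Dict[str, LabeledDistribution]:
    """Per-label ('up'/'down') histograms normalized by the *total* count."""
    x = np.asarray(series, float).ravel()
    lab = np.asarray(labels, bool).ravel()
    if x.shape != lab.shape:
        raise ValueError("series and labels must align")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    hi = max(hi, lo + bin_width)
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    out = {}
    for name, mask in (("up", lab), ("down", ~lab)):
        counts, _ = np.histogram(x[mask], bins=edges)
        out[name] = LabeledDistribution(edges, counts / x.size, label=name)
    return out


@dataclass
class SpectralSummary:
    freqs: np.ndarray         # Hz
    psd_mean: np.ndarray      # (mV)^2/Hz, averaged over windows then trials
    psd_sd: np.ndarray        # dispersion across trials
    psd_trials: np.ndarray = field(repr=False, default=None)  # (n, F)

    @property
    def db(self) -> np.ndarray:
        """Mean PSD in decibels relative to 1 (mV)^2/Hz: ``log10(P/Pr)``."""
        return to_db(self.psd_mean)


def to_db(psd: np.ndarray, p_ref: float = 1.0) -> np.ndarray:
    return np.log10(np.asarray(psd, float) / p_ref)


def spectrogram(x: np.ndarray, dt_ms: float, window_s: float = 2.0,
                overlap: float = 0.9) -> SpectralSummary:
    """Hann-tapered, 90%-overlap Welch PSD averaged over windows and trials.

    ``x`` is (n_trials, n_samples); the trial must be at least one window
    long.  Frequency resolution with 2 s windows is 0.5 Hz.
    """
    x = np.atleast_2d(np.asarray(x, float))
    fs = 1000.0 / dt_ms
    nperseg = int(round(window_s * fs))
    if nperseg > x.shape[-1]:
        raise ValueError("window longer than the signal")
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=int(round(overlap * nperseg)),
                              detrend=False, axis=-1)
    return SpectralSummary(freqs, psd.mean(axis=0), psd.std(axis=0),
                           psd_trials=psd)


def band_ratio(freqs: np.ndarray, psd_trials: np.ndarray,
               low_hz: float = 4.0, high_hz: float = 30.0) -> np.ndarray:
    """Per-trial log10 ratio of summed power above ``high_hz`` to below
    ``low_hz``."""
    psd_trials = np.atleast_2d(psd_trials)
    low = psd_trials[:, freqs < low_hz].sum(axis=1)
    high = psd_trials[:, freqs > high_hz].sum(axis=1)
    if np.any(low <= 0):
        raise ZeroDivisionError("zero power in the low band")
    return np.log10(high / low)


def band_ratio_from(x: np.ndarray, dt_ms: float, **kw) -> np.ndarray:
    spec = spectrogram(x, dt_ms)
    return band_ratio(spec.freqs, spec.psd_trials, **kw)
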