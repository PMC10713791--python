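"""Filtering, band decomposition, windowing and per-window features.

Recordings are notch-filtered around the mains frequency, band-passed to
0.05–47 Hz, split into the five canonical EEG bands (delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–47 Hz), cut into non-overlapping 1-s
windows, and summarized per window as either microstate statistics
(K(K+3) values per band; 40 with K=5), differential entropy (one value per
channel) or band power (one per channel).  Per-band vectors are fused by
concatenation in delta→gamma order (5 × 40 = 200 for microstate features).

Filters are zero-phase 4th-order Butterworth (forward-backward second-order
sections).  Differential entropy assumes per-window Gaussianity:
h = ½ ln(2πe σ̂²) nats, with σ̂² the sample variance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording
from .microstate import MicrostateSegmentation, MicrostateStats, microstate_statistics

logger = logging.getLogger(__name__)

#: variance floor for the differential-entropy zero-variance guard
DE_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError("need 0 <= low < high")


#: the five canonical bands; gamma capped at the 47 Hz anti-alias edge
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 47.0),
)
BAND_ORDER = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class FeatureVector:
    values: np.ndarray
    kind: str  # "microstate" | "de" | "psd"
    bands: tuple[str, ...]
    subject: object = None
    label: object = None
    window: int | None = None


def _check_band(low: float, high: float, sampling_rate: float) -> None:
    nyq = sampling_rate / 2.0
    if not 0 <= low < high <= nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid at fs={sampling_rate}")


def _filtered(rec: EEGRecording, sos: np.ndarray) -> EEGRecording:
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(
        data=data, sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels), subject=rec.subject,
        label=rec.label, state_labels=rec.state_labels,
    )


def notch_filter(
    recording: EEGRecording, low: float = 49.0, high: float = 51.0, order: int = 4
) -> EEGRecording:
    """Zero-phase band-stop, default 49–51 Hz (mains interference)."""
    _check_band(low, high, recording.sampling_rate)
    sos = sps.butter(order, [low, high], btype="bandstop",
                     fs=recording.sampling_rate, output="sos")
    return _filtered(recording, sos)


def bandpass_filter(
    recording: EEGRecording, low: float = 0.05, high: float = 47.0, order: int = 4
) -> EEGRecording:
    """Zero-phase band-pass, default 0.05–47 Hz."""
    _check_band(low, high, recording.sampling_rate)
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=recording.sampling_rate, output="sos")
    return _filtered(recording, sos)


def band_split(
    recording: EEGRecording, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, EEGRecording]:
    """Filter a recording into the named frequency bands."""
    return {
        b.name: bandpass_filter(recording, b.low, b.high) for b in bands
    }


def window_segments(
    n_samples: int, sampling_rate: float, window_s: float = 1.0, overlap: float = 0.0
) -> list[slice]:
    """Slice indices for fixed-length windows; the trailing partial is dropped."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    win = int(round(window_s * sampling_rate))
    stride = max(1, int(round(win * (1.0 - overlap))))
    if win > n_samples:
        logger.warning("window longer than recording; no windows produced")
        return []
    starts = range(0, n_samples - win + 1, stride)
    return [slice(s, s + win) for s in starts]


def differential_entropy(window: np.ndarray) -> np.ndarray:
    """Per-channel DE in nats under a Gaussian model: ½ ln(2πe σ̂²).

    Zero-variance channels are floored at a tiny ε instead of −∞.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] < 2:
        raise ValueError("window must have at least 2 samples")
    var = window.var(axis=1, ddof=1)
    flagged = var <= 0
    if np.any(flagged):
        logger.warning("zero-variance channel(s) in DE; flooring variance")
        var = np.maximum(var, DE_VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def band_psd(
    window: np.ndarray, band: BandDefinition, sampling_rate: float
) -> np.ndarray:
    """Per-channel power within ``band`` via the periodogram (integral of the
    one-sided PSD over the band)."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    _check_band(band.low, band.high, sampling_rate)
    freqs, psd = sps.periodogram(window, fs=sampling_rate, axis=1)
    mask = (freqs >= band.low) & (freqs <= band.high)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    return psd[:, mask].sum(axis=1) * df


def microstate_features_per_window(
    segmentation: MicrostateSegmentation | np.ndarray,
    k: int,
    sampling_rate: float | None = None,
) -> np.ndarray:
    """Flatten one window's microstate statistics into a K(K+3) vector.

    Order (documented contract): coverage (K), mean duration (K),
    occurrence (K), transition-matrix rows (K²).  With K=5 this is 40.
    """
    stats = microstate_statistics(segmentation, k, sampling_rate)
    return stats_to_vector(stats)


def stats_to_vector(stats: MicrostateStats) -> np.ndarray:
    return np.concatenate(
        [stats.coverage, stats.duration, stats.occurrence, stats.transition.ravel()]
    )


def feature_length(kind: str, k: int, n_channels: int) -> int:
    """Expected per-band feature length for a given kind."""
    if kind == "microstate":
        return k * (k + 3)
    if kind in ("de", "psd"):
        return n_channels
    raise ValueError(f"unknown feature kind {kind!r}")


def fuse_bands(per_band: dict[str, np.ndarray], kind: str = "microstate") -> np.ndarray:
    """Concatenate per-band vectors in canonical delta→gamma order.

    Bands absent from :data:`BAND_ORDER` (e.g. a broadband-only analysis)
    are appended alphabetically after the canonical ones.
    """
    lengths = {v.shape[-1] for v in per_band.values()}
    if len(lengths) > 1:
        raise ValueError("cannot fuse bands with mismatched feature lengths")
    canonical = [b for b in BAND_ORDER if b in per_band]
    extra = sorted(set(per_band) - set(canonical))
    return np.concatenate([per_band[b] for b in canonical + extra])
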