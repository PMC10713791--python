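"""EEG microstate analysis: GFP, peak-map clustering, GEV/CV model selection,
backfitting, temporal smoothing and the four microstate statistics.

The microstate model treats multichannel EEG as a sequence of K quasi-stable
prototype topographies.  Candidate topographies are taken at local maxima of
the global field power (GFP), where the signal-to-noise ratio is highest,
and clustered with a K-means-style algorithm.  The number of states K is
chosen with the global explained variance (GEV) and the cross-validation
(CV) criterion.  The winning prototypes are then fitted back to every time
sample, short segments are smoothed away, and four statistics are computed
per state: time coverage, mean duration, occurrence rate and the
segment-level transition matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: default minimum spacing between GFP peaks, in milliseconds
DEFAULT_MIN_PEAK_DISTANCE_MS = 10.0
#: default minimum microstate segment length for smoothing, in milliseconds
DEFAULT_SMOOTH_MS = 30.0
#: dataset-level GEV threshold used when selecting the number of states
DEFAULT_GEV_THRESHOLD = 0.85
#: per-subject GEV threshold (representative-map selection uses a looser bar)
SUBJECT_GEV_THRESHOLD = 0.70


@dataclass
class GFPSeries:
    """Global field power trace with its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray
    sampling_rate: float


@dataclass
class PrototypeSet:
    """K microstate prototype maps (zero-mean, unit-norm rows) plus fit metadata."""

    maps: np.ndarray
    k: int
    gev_total: float
    cv_value: float
    polarity_invariant: bool = False

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != self.k:
            raise ValueError("maps row count must equal k")


@dataclass
class MicrostateSegmentation:
    """Per-sample state labels with fit correlations."""

    labels: np.ndarray
    correlations: np.ndarray
    sampling_rate: float
    smoothed: bool = False
    # full K x n_samples matrix of fit values, kept for smoothing decisions
    all_correlations: np.ndarray | None = None


@dataclass
class MicrostateStats:
    """Coverage, duration (ms), occurrence (1/s) and transition probabilities."""

    coverage: np.ndarray
    duration: np.ndarray
    occurrence: np.ndarray
    transition: np.ndarray


def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Remove the spatial mean and scale each row to unit Euclidean norm."""
    maps = _center(np.atleast_2d(np.asarray(maps, dtype=float)))
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a spatially constant map")
    return maps / norms


def spatial_correlation(data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between samples and prototype maps.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` array.
    maps:
        ``(k, n_channels)`` prototypes.

    Returns
    -------
    ``(k, n_samples)`` correlation matrix; zero-variance samples give 0.
    """
    x = _center(np.asarray(data, dtype=float).T)  # samples x channels
    m = normalize_maps(maps)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x @ m.T) / xn
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return corr.T


def compute_gfp(
    data: np.ndarray,
    sampling_rate: float,
    min_peak_distance_ms: float = DEFAULT_MIN_PEAK_DISTANCE_MS,
) -> GFPSeries:
    """Global field power: spatial standard deviation across channels.

    GFP(t) = sqrt( (1/C) * sum_i (V_i(t) - Vbar(t))^2 ), with Vbar the
    instantaneous spatial mean.  Peaks are strict local maxima at least
    ``min_peak_distance_ms`` apart.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    gfp = data.std(axis=0, ddof=0)
    distance = max(1, int(round(min_peak_distance_ms / 1000.0 * sampling_rate)))
    peaks, _ = find_peaks(gfp, distance=distance)
    return GFPSeries(values=gfp, peak_indices=peaks, sampling_rate=sampling_rate)


def peak_maps(data: np.ndarray, gfp: GFPSeries) -> np.ndarray:
    """Extract the topographies at the GFP peaks, one row per peak."""
    return np.asarray(data, dtype=float).T[gfp.peak_indices]


def _assign(maps_n: np.ndarray, templates: np.ndarray, polarity_invariant: bool):
    """Return (labels, similarity) for unit-norm maps against unit-norm templates.

    Euclidean argmin on unit vectors is equivalent to cosine argmax, which is
    what the plain (polarity-sensitive) mode uses; the polarity-invariant
    mode ranks by absolute cosine.
    """
    sim = maps_n @ templates.T
    score = np.abs(sim) if polarity_invariant else sim
    labels = np.argmax(score, axis=1)
    return labels, sim[np.arange(len(labels)), labels]


def cluster_microstates(
    maps: np.ndarray,
    k: int,
    n_init: int = 20,
    max_iter: int = 300,
    polarity_invariant: bool = False,
    seed: int = 0,
) -> PrototypeSet:
    """Cluster GFP-peak topographies into ``k`` microstate prototypes.

    A modified K-means: maps are spatially centered and unit-normalized,
    assignment is nearest-template (Euclidean, or absolute spatial
    correlation when ``polarity_invariant``), and centroids are renormalized
    after every update.  The best of ``n_init`` random restarts by total GEV
    is returned.  Empty clusters are re-seeded from the worst-fitting map.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n_maps, n_ch = maps.shape
    if n_maps < k:
        raise ValueError(f"need at least k={k} maps, got {n_maps}")
    maps_n = normalize_maps(maps)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_init)):
        templates = maps_n[rng.choice(n_maps, size=k, replace=False)].copy()
        labels = np.full(n_maps, -1)
        for _ in range(max_iter):
            new_labels, fit = _assign(maps_n, templates, polarity_invariant)
            # re-seed empty clusters from the worst-fitting maps
            badness = -(np.abs(fit) if polarity_invariant else fit)
            order = np.argsort(badness)[::-1]
            next_worst = 0
            for j in range(k):
                if not np.any(new_labels == j):
                    worst = int(order[next_worst])
                    next_worst += 1
                    logger.debug("re-seeding empty cluster %d from map %d", j, worst)
                    templates[j] = maps_n[worst]
                    new_labels[worst] = j
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = maps_n[labels == j]
                if members.shape[0] == 0:
                    continue
                if polarity_invariant:
                    signs = np.sign(members @ templates[j])
                    signs[signs == 0] = 1.0
                    members = members * signs[:, None]
                templates[j] = normalize_maps(members.mean(axis=0))[0]
        gev = compute_gev(maps.T, templates, labels)
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), labels.copy())

    gev, templates, labels = best
    cv = np.nan
    if n_ch > k + 1:
        cv = compute_cv(maps.T, templates, labels, n_channels=n_ch, k=k)
    return PrototypeSet(
        maps=templates, k=k, gev_total=float(gev), cv_value=float(cv),
        polarity_invariant=polarity_invariant,
    )


def compute_gev(
    data: np.ndarray,
    prototypes: np.ndarray,
    labels: np.ndarray,
    gfp: np.ndarray | None = None,
) -> float:
    """Global explained variance of a labelled segmentation.

    GEV = sum_i (corr(x_i, p_{l_i}) * GFP_i)^2 / sum_i GFP_i^2, where corr is
    the spatial Pearson correlation.  Squaring makes the measure blind to
    topography polarity.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if gfp is None:
        gfp = data.std(axis=0, ddof=0)
    total = float(np.sum(gfp**2))
    if total == 0:
        raise ValueError("total GFP is zero; cannot compute GEV")
    corr = spatial_correlation(data, prototypes)
    fit = corr[labels, np.arange(data.shape[1])]
    return float(np.sum((fit * gfp) ** 2) / total)


def compute_cv(
    data: np.ndarray,
    prototypes: np.ndarray,
    labels: np.ndarray,
    n_channels: int,
    k: int,
) -> float:
    """Cross-validation criterion for microstate model selection.

    Residual noise variance sigma^2 = sum_i (x_i'x_i - (a_{l_i}'x_i)^2) / (N(C-1))
    with a the unit-norm assigned prototype, scaled by the degrees-of-freedom
    penalty ((C-1)/(C-K-1))^2.  Lower is better; requires C > K + 1.
    """
    if n_channels <= k + 1:
        raise ValueError("CV undefined unless n_channels > k + 1")
    x = _center(np.asarray(data, dtype=float).T)  # samples x channels
    a = normalize_maps(prototypes)
    proj = np.einsum("ij,ij->i", x, a[np.asarray(labels)])
    resid = np.einsum("ij,ij->i", x, x) - proj**2
    n = x.shape[0]
    sigma2 = float(resid.sum() / (n * (n_channels - 1)))
    factor = ((n_channels - 1) / (n_channels - k - 1)) ** 2
    return sigma2 * factor


def select_k(
    maps: np.ndarray,
    k_range: range | list[int],
    gev_threshold: float = DEFAULT_GEV_THRESHOLD,
    n_init: int = 20,
    max_iter: int = 300,
    polarity_invariant: bool = False,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of microstates from GEV and CV over ``k_range``.

    Rule: among k whose GEV reaches ``gev_threshold``, prefer the smallest k
    at a local minimum of CV; if none is a local minimum, the smallest k over
    threshold; if no k reaches the threshold, the k with maximal GEV.
    Returns the chosen k and the per-k table of GEV/CV values.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    rows = []
    for k in ks:
        ps = cluster_microstates(
            maps, k, n_init=n_init, max_iter=max_iter,
            polarity_invariant=polarity_invariant, seed=seed,
        )
        rows.append({"k": k, "gev": ps.gev_total, "cv": ps.cv_value})
    table = pd.DataFrame(rows)

    cv = table["cv"].to_numpy()
    local_min = np.ones(len(ks), dtype=bool)
    for i in range(len(ks)):
        if i > 0 and np.isfinite(cv[i - 1]) and cv[i - 1] < cv[i]:
            local_min[i] = False
        if i < len(ks) - 1 and np.isfinite(cv[i + 1]) and cv[i + 1] < cv[i]:
            local_min[i] = False
    over = table["gev"].to_numpy() >= gev_threshold
    if over.any():
        both = over & local_min
        idx = int(np.argmax(both)) if both.any() else int(np.argmax(over))
    else:
        idx = int(np.argmax(table["gev"].to_numpy()))
    return ks[idx], table


def backfit(
    data: np.ndarray,
    prototypes: PrototypeSet | np.ndarray,
    sampling_rate: float,
    polarity_invariant: bool = True,
) -> MicrostateSegmentation:
    """Assign every sample to its best-correlating prototype.

    Default is polarity-invariant (|correlation|), matching the sign-blind
    squared-correlation fit measure; set ``polarity_invariant=False`` for
    signed assignment.
    """
    maps = prototypes.maps if isinstance(prototypes, PrototypeSet) else prototypes
    corr = spatial_correlation(data, maps)
    score = np.abs(corr) if polarity_invariant else corr
    labels = np.argmax(score, axis=0)
    winning = score[labels, np.arange(score.shape[1])]
    return MicrostateSegmentation(
        labels=labels, correlations=winning, sampling_rate=sampling_rate,
        all_correlations=score,
    )


def label_segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Decompose a label sequence into ``(start, stop, label)`` runs (stop exclusive)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def smooth_labels(
    segmentation: MicrostateSegmentation, min_duration_ms: float
) -> MicrostateSegmentation:
    """Reassign segments shorter than ``min_duration_ms`` to a neighbour state.

    A short segment takes the neighbouring label with the higher mean fit
    value over the segment's samples; iterated until no segment below the
    minimum can be changed.  ``min_duration_ms=0`` is the identity.
    """
    if min_duration_ms < 0:
        raise ValueError("min_duration_ms must be >= 0")
    labels = segmentation.labels.copy()
    if min_duration_ms == 0 or labels.size == 0:
        return MicrostateSegmentation(
            labels=labels,
            correlations=segmentation.correlations.copy(),
            sampling_rate=segmentation.sampling_rate,
            smoothed=True,
            all_correlations=segmentation.all_correlations,
        )
    score = segmentation.all_correlations
    min_samples = max(1, int(round(min_duration_ms / 1000.0 * segmentation.sampling_rate)))
    for _ in range(labels.size):  # each pass merges segments; bounded
        segs = label_segments(labels)
        changed = False
        for i, (a, b, lab) in enumerate(segs):
            if b - a >= min_samples:
                continue
            left = segs[i - 1][2] if i > 0 else None
            right = segs[i + 1][2] if i < len(segs) - 1 else None
            if left is None and right is None:
                continue
            if left is None:
                new = right
            elif right is None:
                new = left
            elif score is not None:
                new = left if score[left, a:b].mean() >= score[right, a:b].mean() else right
            else:
                new = left
            if new != lab:
                labels[a:b] = new
                changed = True
                break  # re-derive segments after every merge
        if not changed:
            break
    out = MicrostateSegmentation(
        labels=labels,
        correlations=segmentation.correlations.copy(),
        sampling_rate=segmentation.sampling_rate,
        smoothed=True,
        all_correlations=segmentation.all_correlations,
    )
    return out


def microstate_statistics(
    segmentation: MicrostateSegmentation | np.ndarray,
    k: int,
    sampling_rate: float | None = None,
) -> MicrostateStats:
    """Coverage, mean duration, occurrence rate and transition matrix.

    * coverage_k — fraction of samples labelled k (sums to 1);
    * duration_k — mean segment length in ms (0 for absent states);
    * occurrence_k — segments of state k per second of data;
    * transition — segment-level counts row-normalized (self-transitions are
      impossible at segment level; rows of never-left states stay all-zero).

    For present states the identity occurrence_k * duration_k =
    1000 * coverage_k holds exactly.
    """
    if isinstance(segmentation, MicrostateSegmentation):
        labels = segmentation.labels
        fs = segmentation.sampling_rate
    else:
        labels = np.asarray(segmentation)
        if sampling_rate is None:
            raise ValueError("sampling_rate required when passing a bare label array")
        fs = sampling_rate
    if labels.size == 0:
        raise ValueError("empty label sequence")
    n = labels.size
    coverage = np.bincount(labels, minlength=k)[:k] / n

    segs = label_segments(labels)
    duration = np.zeros(k)
    occurrence = np.zeros(k)
    counts = np.zeros(k)
    for a, b, lab in segs:
        duration[lab] += b - a
        counts[lab] += 1
    present = counts > 0
    duration[present] = duration[present] / counts[present] / fs * 1000.0
    occurrence = counts / (n / fs)

    transition = np.zeros((k, k))
    for (_, _, src), (_, _, dst) in zip(segs[:-1], segs[1:]):
        transition[src, dst] += 1
    row_sums = transition.sum(axis=1, keepdims=True)
    np.divide(transition, row_sums, out=transition, where=row_sums > 0)
    return MicrostateStats(
        coverage=coverage, duration=duration, occurrence=occurrence, transition=transition
    )
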