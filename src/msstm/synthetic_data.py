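"""Synthetic EEG generator with known ground truth.

Emulates the structure of an odor/video emotion EEG study (28 scalp
channels at 250 Hz, three emotion classes, ~13 subjects) without any real
data: K shared prototype topographies, a semi-Markov state sequence whose
transition matrix and dwell times are class-conditional, a half-sine GFP
amplitude envelope per state segment, additive Gaussian sensor noise, a toy
spherical lead field for source simulation, and per-subject affine "style"
distortions that act on extracted feature vectors.

Class information is injected only through the microstate dynamics
(transitions and dwell times); the prototype maps themselves are shared by
all classes and subjects, so microstate statistics — not topography shape —
carry the discriminative signal.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import EEGRecording

logger = logging.getLogger(__name__)

#: offsets used to fan the global seed out into independent streams
_SEED_LEADFIELD = 101
_SEED_PROTOTYPES = 211
_SEED_STYLES = 307
_SEED_TRIALS = 401


@dataclass
class GeneratorConfig:
    """Study-level parameters of the synthetic dataset.

    Defaults mirror a 28-channel, 250 Hz, three-class (positive / neutral /
    negative) recording setup with five microstates.
    """

    n_subjects: int = 13
    n_classes: int = 3
    n_channels: int = 28
    sampling_rate: float = 250.0
    n_states: int = 5
    n_trials: int = 4
    trial_duration: float = 8.0
    snr: float = 10.0
    style_strength: float = 2.0
    trial_jitter: float = 0.1
    dwell_law: str = "truncnorm"  # or "geometric"
    feature_dim: int = 40  # K(K+3) with K=5; dimension styles act on
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_classes", "n_channels", "n_states", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.dwell_law not in ("truncnorm", "geometric"):
            raise ValueError("dwell_law must be 'truncnorm' or 'geometric'")


@dataclass
class LeadField:
    """Forward gain matrix mapping sources to sensors."""

    gain: np.ndarray  # (n_sensors, n_sources)
    source_positions: np.ndarray  # (n_sources, 3)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.shape[0] < 2:
            raise ValueError("need at least 2 sensors")
        if np.any(np.linalg.norm(self.gain, axis=0) == 0):
            raise ValueError("lead field contains an all-zero column")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.gain.shape[0])]

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    prototypes: np.ndarray  # (K, n_channels), zero-mean unit-norm rows
    class_transition: np.ndarray  # (n_classes, K, K), row-stochastic, zero diag
    class_duration_means: np.ndarray  # (n_classes, K) mean dwell in ms
    subject_styles: list[tuple[np.ndarray, np.ndarray]]  # per-subject (A, b)
    state_sequences: dict = field(default_factory=dict)  # (subject, cls, trial) -> labels


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform grid of ``n`` points on a sphere (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return radius * pts


def make_lead_field(
    n_channels: int, n_sources: int, seed: int, max_retries: int = 5
) -> LeadField:
    """Build a toy spherical-head lead field with unit-norm columns.

    Sensors sit on a unit sphere, sources on an interior spherical grid with
    fixed (radial) orientation; the gain falls off with squared
    sensor-source distance.  Full row rank is verified and the geometry is
    perturbed on failure.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if n_sources < n_channels:
        raise ValueError("need n_sources >= n_channels")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        sensors = fibonacci_sphere(n_channels, radius=1.0)
        sources = fibonacci_sphere(n_sources, radius=0.85)
        if attempt > 0:
            sources = sources + 0.01 * rng.standard_normal(sources.shape)
        d2 = np.sum((sensors[:, None, :] - sources[None, :, :]) ** 2, axis=2)
        gain = 1.0 / (0.05 + d2)
        gain = gain / np.linalg.norm(gain, axis=0, keepdims=True)
        if np.linalg.matrix_rank(gain) == n_channels:
            return LeadField(gain=gain, source_positions=sources)
        logger.warning("lead field rank-deficient; retrying with perturbed geometry")
    raise RuntimeError("could not construct a full-row-rank lead field")


def make_prototypes(n_states: int, n_channels: int, seed: int) -> np.ndarray:
    """Random mutually-orthogonal zero-mean unit-norm topographies.

    Orthogonality makes the states identifiable by clustering, which is the
    regime the microstate model assumes (distinct quasi-stable maps).
    """
    if n_states >= n_channels:
        raise ValueError("need n_states < n_channels for zero-mean orthogonal maps")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_channels, n_states))
    x -= x.mean(axis=0, keepdims=True)  # project into the average-reference space
    q, _ = np.linalg.qr(x)
    maps = q.T[:n_states]
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


def class_dynamics(
    n_classes: int, n_states: int, base_dwell_ms: float = 100.0, margin: float = 0.1
):
    """Class-conditional transition matrices and dwell means.

    Class ``c`` favours the transition i -> (i + 1 + c) mod K with
    probability mass ``0.15 + margin`` (rest uniform), and its dwell means
    tilt linearly across states — class 0 flat, later classes increasingly
    skewed in alternating directions.  ``margin`` controls how far apart the
    class-conditional statistics are.
    """
    k = n_states
    if k < 2:
        trans = np.zeros((n_classes, 1, 1))
        dwell = np.full((n_classes, 1), base_dwell_ms)
        return trans, dwell
    trans = np.zeros((n_classes, k, k))
    for c in range(n_classes):
        for i in range(k):
            others = [j for j in range(k) if j != i]
            fav = (i + 1 + c) % k
            if fav == i:
                fav = (i + 1) % k
            base = (1.0 - (1.0 / (k - 1) + margin)) / (k - 2) if k > 2 else 0.0
            for j in others:
                trans[c, i, j] = base
            trans[c, i, fav] = 1.0 / (k - 1) + margin
            trans[c, i] /= trans[c, i].sum()
    dwell = np.zeros((n_classes, k))
    for c in range(n_classes):
        if c == 0:
            dwell[c] = base_dwell_ms
        else:
            spread = 0.4 * base_dwell_ms
            ramp = np.linspace(-spread, spread, k)
            dwell[c] = base_dwell_ms + (ramp if c % 2 else -ramp) * (1 + (c - 1) // 2)
    return trans, np.maximum(dwell, 20.0)


def simulate_state_sequence(
    transition: np.ndarray,
    dwell_means: np.ndarray,
    length: int,
    sampling_rate: float,
    seed: int,
    dwell_law: str = "truncnorm",
) -> np.ndarray:
    """Semi-Markov label sequence: dwell per segment, then a jump.

    Dwell times are truncated-normal (sd = mean/4, minimum 2 samples) by
    default, or geometric; successive segment labels are drawn from the
    row-stochastic ``transition`` matrix, which must have a zero diagonal.
    """
    transition = np.asarray(transition, dtype=float)
    k = transition.shape[0]
    dwell_means = np.broadcast_to(np.asarray(dwell_means, dtype=float), (k,))
    if np.any(dwell_means <= 0):
        raise ValueError("dwell means must be positive")
    if k > 1:
        if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(np.diag(transition) != 0):
            raise ValueError("transition diagonal must be zero (segment-level chain)")
    rng = np.random.default_rng(seed)
    labels = np.empty(length, dtype=int)
    state = int(rng.integers(k))
    t = 0
    while t < length:
        mean_samples = dwell_means[state] / 1000.0 * sampling_rate
        if dwell_law == "geometric":
            dwell = rng.geometric(min(1.0, 1.0 / mean_samples))
        else:
            dwell = int(round(rng.normal(mean_samples, mean_samples / 4.0)))
        dwell = max(2, int(dwell))
        labels[t : t + dwell] = state
        t += dwell
        if k > 1:
            state = int(rng.choice(k, p=transition[state]))
    return labels


def _segment_bounds(labels: np.ndarray):
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return starts, stops


def simulate_recording(
    prototypes: np.ndarray,
    labels: np.ndarray,
    sampling_rate: float,
    snr: float,
    seed: int,
    subject=None,
    class_label=None,
) -> EEGRecording:
    """Render a state-label sequence into a noisy multichannel recording.

    The clean signal at sample t is the active prototype scaled by a
    half-sine amplitude envelope over its segment (so the GFP peaks
    mid-segment, as the GFP-peak clustering pipeline requires), plus white
    Gaussian channel noise scaled so that signal RMS / noise RMS = ``snr``.
    ``snr=np.inf`` gives a noiseless recording.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    prototypes = np.atleast_2d(np.asarray(prototypes, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= prototypes.shape[0]:
        raise ValueError("labels outside prototype range")
    env = np.empty(labels.size)
    starts, stops = _segment_bounds(labels)
    for a, b in zip(starts, stops):
        u = (np.arange(b - a) + 0.5) / (b - a)
        env[a:b] = np.sin(np.pi * u)
    clean = prototypes[labels].T * env  # channels x samples
    rng = np.random.default_rng(seed)
    if np.isinf(snr):
        data = clean
    else:
        signal_rms = np.sqrt(np.mean(clean**2))
        noise = rng.standard_normal(clean.shape) * (signal_rms / snr)
        data = clean + noise
    return EEGRecording(
        data=data,
        sampling_rate=sampling_rate,
        subject=subject,
        label=class_label,
        state_labels=labels.copy(),
    )


def make_style_maps(
    n_subjects: int, dim: int, strength: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-subject affine feature-space distortions (A, b).

    Inter-subject EEG feature variability is dominated by per-feature gain
    and offset differences (amplitude scales, duration biases), with only
    mild cross-feature mixing, so A = diag(exp(strength/2 * n)) ·
    (I + strength/3 * G / sqrt(dim)) and b = strength/2 * g, all entries
    standard normal.  At ``strength=0`` every subject is exactly the
    identity.  The maps act on z-scored feature vectors, where ``strength``
    ≈ 1 distorts by about one within-class standard deviation.
    """
    rng = np.random.default_rng(seed)
    styles = []
    for _ in range(n_subjects):
        gains = np.exp(0.5 * strength * rng.standard_normal(dim))
        mix = np.eye(dim) + (strength / 3.0) * rng.standard_normal((dim, dim)) / np.sqrt(dim)
        a = np.diag(gains) @ mix
        b = 0.5 * strength * rng.standard_normal(dim)
        styles.append((a, b))
    return styles


@dataclass
class SyntheticDataset:
    """Bundle of recordings with the generating ground truth."""

    recordings: list[EEGRecording]
    ground_truth: GroundTruth
    config: GeneratorConfig

    @property
    def subjects(self) -> list[int]:
        return sorted({r.subject for r in self.recordings})


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full subject x class x trial synthetic dataset.

    Classes differ only in their transition matrices and dwell-time means;
    trial-level jitter perturbs the dwell means multiplicatively.  Subject
    style maps are returned in the ground truth and applied downstream in
    feature space (see :func:`msstm.evaluation.stylize_features`).
    """
    fs = config.sampling_rate
    length = int(round(config.trial_duration * fs))
    prototypes = make_prototypes(
        config.n_states, config.n_channels, config.seed + _SEED_PROTOTYPES
    )
    trans, dwell = class_dynamics(config.n_classes, config.n_states)
    styles = make_style_maps(
        config.n_subjects, config.feature_dim, config.style_strength,
        config.seed + _SEED_STYLES,
    )
    recordings = []
    sequences = {}
    for s in range(config.n_subjects):
        for c in range(config.n_classes):
            for t in range(config.n_trials):
                offset = ((s * config.n_classes + c) * config.n_trials + t) * 7
                trial_seed = config.seed + _SEED_TRIALS + offset
                rng = np.random.default_rng(trial_seed)
                jitter = 1.0 + config.trial_jitter * rng.standard_normal(config.n_states)
                dwell_t = np.maximum(dwell[c] * np.abs(jitter), 20.0)
                labels = simulate_state_sequence(
                    trans[c], dwell_t, length, fs, seed=trial_seed + 1,
                    dwell_law=config.dwell_law,
                )
                rec = simulate_recording(
                    prototypes, labels, fs, config.snr, seed=trial_seed + 2,
                    subject=s, class_label=c,
                )
                recordings.append(rec)
                sequences[(s, c, t)] = labels
    gt = GroundTruth(
        prototypes=prototypes,
        class_transition=trans,
        class_duration_means=dwell,
        subject_styles=styles,
        state_sequences=sequences,
    )
    return SyntheticDataset(recordings=recordings, ground_truth=gt, config=config)


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a dataset as one ``.npy`` per recording plus JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(dataset.config), "recordings": []}
    for i, rec in enumerate(dataset.recordings):
        name = f"rec{i:04d}"
        np.save(out / f"{name}.npy", rec.data)
        np.save(out / f"{name}_states.npy", rec.state_labels)
        meta["recordings"].append(
            {
                "file": f"{name}.npy",
                "subject": int(rec.subject),
                "label": int(rec.label),
                "sampling_rate": rec.sampling_rate,
                "channel_labels": rec.channel_labels,
            }
        )
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    gt = dataset.ground_truth
    np.savez(
        out / "ground_truth.npz",
        prototypes=gt.prototypes,
        class_transition=gt.class_transition,
        class_duration_means=gt.class_duration_means,
        style_A=np.stack([a for a, _ in gt.subject_styles]),
        style_b=np.stack([b for _, b in gt.subject_styles]),
    )
    return out


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`save_dataset`."""
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    config = GeneratorConfig(**meta["config"])
    recordings = []
    for entry in meta["recordings"]:
        data = np.load(src / entry["file"])
        states = np.load(src / (entry["file"][:-4] + "_states.npy"))
        recordings.append(
            EEGRecording(
                data=data,
                sampling_rate=entry["sampling_rate"],
                channel_labels=entry["channel_labels"],
                subject=entry["subject"],
                label=entry["label"],
                state_labels=states,
            )
        )
    z = np.load(src / "ground_truth.npz")
    gt = GroundTruth(
        prototypes=z["prototypes"],
        class_transition=z["class_transition"],
        class_duration_means=z["class_duration_means"],
        subject_styles=[(a, b) for a, b in zip(z["style_A"], z["style_b"])],
    )
    return SyntheticDataset(recordings=recordings, ground_truth=gt, config=config)
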