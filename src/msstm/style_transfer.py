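"""Style transfer mapping (STM): nearest-prototype affine domain adaptation.

Cross-subject EEG features drift because every subject imposes their own
"style" on the feature distribution.  STM learns one affine map (A, b) per
target subject that pulls target-domain feature vectors toward source-domain
class prototypes, so a classifier trained on the source subjects applies to
the adapted target.

Given pairs (x_i, y_i) — y_i a target sample, x_i the source prototype it
was matched to — with confidences f_i ∈ [0, 1], the map minimizes

    Σ_i f_i ‖A y_i + b − x_i‖²  +  β ‖A − I‖_F²

which has a closed form: eliminating b via the weighted means and writing
ỹ, x̃ for centered variables,

    A = (Σ f_i x̃_i ỹ_iᵀ + βI)(Σ f_i ỹ_i ỹ_iᵀ + βI)⁻¹,   b = x̄_w − A ȳ_w.

β balances transfer against staying near the identity; it may be fixed
(default 0.2) or set from the data as β = β̃ · Tr(Σ f_i y_i y_iᵀ)/M with
β̃ ∈ [1, 3].  Pairing is label-blind: each target sample is matched to its
nearest prototype over all classes, since target labels are unknown in the
cross-subject setting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE = 0.8
DEFAULT_BETA = 0.2
DEFAULT_PROTOTYPES_PER_CLASS = 3


@dataclass
class PrototypeModel:
    """Per-class K-means centers used as pairing anchors."""

    prototypes: dict  # class label -> (n_i, M) array
    n_per_class: dict  # class label -> int

    @property
    def dim(self) -> int:
        return next(iter(self.prototypes.values())).shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All prototypes stacked, with their class labels."""
        mats, labs = [], []
        for c, p in self.prototypes.items():
            mats.append(p)
            labs.extend([c] * p.shape[0])
        return np.vstack(mats), np.asarray(labs)


@dataclass
class StyleMap:
    """Affine feature-space transform y ↦ A y + b."""

    A: np.ndarray
    b: np.ndarray
    beta: float
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A must be finite")


def learn_prototypes(
    features: np.ndarray,
    labels: np.ndarray,
    n_per_class: int = DEFAULT_PROTOTYPES_PER_CLASS,
    seed: int = 0,
) -> PrototypeModel:
    """Cluster each class of source features into ``n_per_class`` centers."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    protos, counts = {}, {}
    for c in np.unique(labels):
        x = features[labels == c]
        n = min(n_per_class, x.shape[0])
        if n < n_per_class:
            logger.warning("class %r has only %d samples; using %d prototypes",
                           c, x.shape[0], n)
        if n == 1:
            centers = x.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=n, n_init=10, random_state=seed)
            km.fit(x)
            centers = km.cluster_centers_
        protos[c] = centers
        counts[c] = n
    return PrototypeModel(prototypes=protos, n_per_class=counts)


def pair_targets(
    targets: np.ndarray,
    model: PrototypeModel,
    confidence: float = DEFAULT_CONFIDENCE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match each target sample to its nearest prototype (Euclidean).

    Returns ``(x, y, f)``: matched prototypes, target samples and
    confidences (the configured constant for every pair).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if not model.prototypes:
        raise ValueError("empty prototype model")
    all_protos, _ = model.stacked()
    if targets.shape[1] != all_protos.shape[1]:
        raise ValueError("feature dimension mismatch with prototype model")
    d2 = ((targets[:, None, :] - all_protos[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    x = all_protos[nearest]
    f = np.full(targets.shape[0], float(confidence))
    return x, targets, f


def compute_beta(
    beta_tilde: float, y: np.ndarray, f: np.ndarray | float = 1.0
) -> float:
    """β = β̃ · Tr(Σ_i f_i y_i y_iᵀ) / M  =  β̃ · Σ_i f_i ‖y_i‖² / M."""
    if beta_tilde < 0:
        raise ValueError("beta_tilde must be >= 0")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    f = np.broadcast_to(np.asarray(f, dtype=float), (y.shape[0],))
    m = y.shape[1]
    return float(beta_tilde * np.sum(f * np.einsum("ij,ij->i", y, y)) / m)


def solve_stm(
    x: np.ndarray, y: np.ndarray, f: np.ndarray | float, beta: float
) -> StyleMap:
    """Closed-form minimizer of the weighted regularized affine objective.

    ``x`` are the anchors (source prototypes), ``y`` the samples to be
    transformed; the returned map sends y toward x.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have identical shapes")
    n, m = y.shape
    f = np.broadcast_to(np.asarray(f, dtype=float), (n,)).copy()
    if beta < 0:
        raise ValueError("beta must be >= 0")
    fsum = f.sum()
    if fsum > 0:
        xbar = (f[:, None] * x).sum(axis=0) / fsum
        ybar = (f[:, None] * y).sum(axis=0) / fsum
    else:
        xbar = np.zeros(m)
        ybar = np.zeros(m)
    xc = x - xbar
    yc = y - ybar
    syy = (f[:, None] * yc).T @ yc + beta * np.eye(m)
    sxy = (f[:, None] * xc).T @ yc + beta * np.eye(m)
    try:
        a = np.linalg.solve(syy.T, sxy.T).T
    except np.linalg.LinAlgError:
        logger.warning("singular STM system; using pseudo-inverse")
        a = sxy @ np.linalg.pinv(syy)
    b = xbar - a @ ybar
    return StyleMap(A=a, b=b, beta=float(beta), confidence=f)


def stm_objective(
    style: StyleMap, x: np.ndarray, y: np.ndarray, f: np.ndarray | float, beta: float
) -> float:
    """Value of Σ f_i‖Ay_i + b − x_i‖² + β‖A−I‖_F² for a candidate map."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    f = np.broadcast_to(np.asarray(f, dtype=float), (y.shape[0],))
    resid = y @ style.A.T + style.b - x
    return float(
        np.sum(f * np.einsum("ij,ij->i", resid, resid))
        + beta * np.linalg.norm(style.A - np.eye(style.A.shape[0])) ** 2
    )


def apply_map(style: StyleMap, features: np.ndarray) -> np.ndarray:
    """Apply y ↦ A y + b row-wise."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    feats = np.atleast_2d(features)
    if feats.shape[1] != style.A.shape[0]:
        raise ValueError("feature dimension does not match style map")
    out = feats @ style.A.T + style.b
    return out[0] if single else out


def fit_style_transfer(
    source_features: np.ndarray,
    source_labels: np.ndarray,
    target_features: np.ndarray,
    n_per_class: int = DEFAULT_PROTOTYPES_PER_CLASS,
    confidence: float = DEFAULT_CONFIDENCE,
    beta: float | None = DEFAULT_BETA,
    beta_tilde: float | None = None,
    seed: int = 0,
) -> tuple[StyleMap, PrototypeModel]:
    """End-to-end STM fit: prototypes → pairing → β → closed-form solve.

    Pass ``beta_tilde`` to use the data-driven β heuristic instead of the
    fixed ``beta``.
    """
    model = learn_prototypes(source_features, source_labels, n_per_class, seed=seed)
    x, y, f = pair_targets(target_features, model, confidence=confidence)
    if beta_tilde is not None:
        beta = compute_beta(beta_tilde, y, f)
    elif beta is None:
        raise ValueError("provide beta or beta_tilde")
    style = solve_stm(x, y, f, beta)
    return style, model
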