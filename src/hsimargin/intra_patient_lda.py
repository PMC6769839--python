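"""Personalized (intra-patient) ensemble LDA.

The intra-patient protocol emulates on-the-fly, per-patient model building in
the operating room: an ensemble of 500 linear discriminant learners is
trained and validated in 5 stratified pixel-level folds on a patient's own
primary-tumor (T) and all-normal (N) specimens, then tested on the same
patient's tumor-involved margin (TN) specimen.

Each learner is a two-class Gaussian discriminant with a shared, shrunk
pooled covariance ``S_hat = (1 - g) S + g diag(S)`` and empirical priors; its
posterior is the usual logistic of the linear discriminant score. Learners
are bagged: each is fit on a bootstrap bag drawn from the training folds, and
the ensemble score is the mean posterior over learners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .hypercube_io import NORMAL, TUMOR, ConfigurationError, SpecimenScene, trim_tissue_edge

__all__ = [
    "PixelFeatureSet",
    "EnsembleConfig",
    "LDALearner",
    "FittedEnsemble",
    "extract_pixel_features",
    "fit_lda",
    "train_intra_patient",
    "predict_map",
    "DEFAULT_EDGE_TRIM_PX",
]

#: tissue-edge trim applied before any training or evaluation (0.25 mm)
DEFAULT_EDGE_TRIM_PX = 10


@dataclass
class PixelFeatureSet:
    """Per-pixel spectra with labels and provenance."""

    spectra: np.ndarray  # n x C calibrated reflectance
    labels: np.ndarray  # n, 1 = carcinoma
    scene_ids: np.ndarray  # n, provenance
    coords: np.ndarray  # n x 2 (row, col)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EnsembleConfig:
    n_learners: int = 500
    n_folds: int = 5
    bag_fraction: float = 0.63
    shrinkage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ConfigurationError("n_learners must be >= 1")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ConfigurationError("bag_fraction must be in (0, 1]")
        if not (0.0 <= self.shrinkage <= 1.0):
            raise ConfigurationError("shrinkage must be in [0, 1]")


@dataclass
class LDALearner:
    """One linear discriminant: posterior(x) = sigmoid(w.x + b)."""

    w: np.ndarray
    b: float
    means: np.ndarray  # 2 x C class means (normal, carcinoma)
    priors: np.ndarray
    bag_indices: np.ndarray | None = None  # training-row provenance

    def posterior(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(X @ self.w + self.b, -500.0, 500.0)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FittedEnsemble:
    learners: list
    fold_validation_scores: list  # per fold: (scores, labels)
    config: EnsembleConfig
    n_features: int

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Mean posterior over all learners."""
        W = np.stack([l.w for l in self.learners], axis=1)  # C x L
        b = np.array([l.b for l in self.learners])
        Z = np.clip(X @ W + b, -500.0, 500.0)
        return (1.0 / (1.0 + np.exp(-Z))).mean(axis=1)

    @property
    def validation_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated held-out validation scores and labels over folds."""
        scores = np.concatenate([s for s, _ in self.fold_validation_scores])
        labels = np.concatenate([l for _, l in self.fold_validation_scores])
        return scores, labels


def extract_pixel_features(
    scene: SpecimenScene,
    mask: np.ndarray | None = None,
    *,
    edge_trim_px: int = DEFAULT_EDGE_TRIM_PX,
) -> PixelFeatureSet:
    """One feature row (the calibrated spectrum) per included tissue pixel.

    If ``mask`` is None, the scene's tissue mask eroded by ``edge_trim_px`` is
    used, so unreliable free-edge pixels never enter training or evaluation.
    """
    if mask is None:
        mask = trim_tissue_edge(scene.tissue_mask, edge_trim_px)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("feature extraction mask is empty")
    cube = scene.calibrated()
    ys, xs = np.nonzero(mask)
    spectra = cube.values[ys, xs, :]
    labels = (scene.gt_mask[ys, xs] == TUMOR).astype(int)
    scene_id = f"{scene.meta.patient_id}_{scene.meta.specimen_type}"
    return PixelFeatureSet(
        spectra=spectra,
        labels=labels,
        scene_ids=np.array([scene_id] * len(ys)),
        coords=np.stack([ys, xs], axis=1),
    )


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    shrinkage: float = 0.0,
    bag_indices: np.ndarray | None = None,
) -> LDALearner:
    """Fit one two-class LDA learner with diagonal-shrinkage regularization.

    The discriminant direction is ``w = S_hat^{-1} (mu1 - mu0)`` with
    ``S_hat = (1 - g) S + g diag(S)``, where ``S`` is the pooled within-class
    covariance and ``g`` the shrinkage. The intercept uses empirical class
    priors, so the posterior is the exact two-Gaussian, shared-covariance
    class probability.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ConfigurationError("features must be n x C with one label per row")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ConfigurationError("both classes must be present to fit LDA")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    X0c = X[y == 0] - mu0
    X1c = X[y == 1] - mu1
    S = (X0c.T @ X0c + X1c.T @ X1c) / max(len(y) - 2, 1)
    if shrinkage > 0:
        S = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "pooled covariance is singular; set shrinkage > 0 "
            "(e.g. EnsembleConfig(shrinkage=0.1))"
        ) from exc
    priors = np.array([n0, n1]) / len(y)
    b = float(-0.5 * w @ (mu0 + mu1) + np.log(priors[1] / priors[0]))
    return LDALearner(w=w, b=b, means=np.stack([mu0, mu1]), priors=priors,
                      bag_indices=bag_indices)


def _draw_bag(rng, train_idx: np.ndarray, labels: np.ndarray, bag_fraction: float):
    """Bootstrap bag with both classes guaranteed present."""
    if bag_fraction >= 1.0:
        return train_idx
    size = max(2, int(round(bag_fraction * len(train_idx))))
    for _ in range(50):
        bag = rng.choice(train_idx, size=size, replace=True)
        if 0 < labels[bag].sum() < size:
            return bag
    raise ConfigurationError("could not draw a bag containing both classes")


def train_intra_patient(
    t_scene: SpecimenScene,
    n_scene: SpecimenScene,
    config: EnsembleConfig = EnsembleConfig(),
    *,
    edge_trim_px: int = DEFAULT_EDGE_TRIM_PX,
) -> FittedEnsemble:
    """Train the per-patient bagged-LDA ensemble on T and N specimens.

    Pixels from both specimens are pooled and split into ``n_folds``
    stratified folds. Learners are distributed evenly over folds; each is fit
    on a bootstrap bag of its training folds' rows, and held-out validation
    scores (mean posterior of that fold's learners) are recorded per fold for
    operating-point selection.
    """
    if t_scene.meta.patient_id != n_scene.meta.patient_id:
        raise ConfigurationError("T and N scenes must come from the same patient")
    feats_t = extract_pixel_features(t_scene, edge_trim_px=edge_trim_px)
    feats_n = extract_pixel_features(n_scene, edge_trim_px=edge_trim_px)
    X = np.concatenate([feats_t.spectra, feats_n.spectra])
    y = np.concatenate([feats_t.labels, feats_n.labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise ConfigurationError("training pixels contain a single class only")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < config.n_folds:
        raise ConfigurationError(
            f"too few pixels per class for {config.n_folds} folds: "
            f"normal={class_counts[0]}, tumor={class_counts[1]}"
        )
    rng = np.random.default_rng(config.seed)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    per_fold = np.full(config.n_folds, config.n_learners // config.n_folds)
    per_fold[: config.n_learners % config.n_folds] += 1

    learners: list[LDALearner] = []
    fold_scores = []
    for fold, (train_idx, val_idx) in enumerate(skf.split(X, y)):
        fold_learners = []
        for _ in range(per_fold[fold]):
            bag = _draw_bag(rng, train_idx, y, config.bag_fraction)
            fold_learners.append(
                fit_lda(X[bag], y[bag], config.shrinkage, bag_indices=bag)
            )
        if fold_learners:
            val_post = np.mean(
                [l.posterior(X[val_idx]) for l in fold_learners], axis=0
            )
            fold_scores.append((val_post, y[val_idx]))
            learners.extend(fold_learners)
    return FittedEnsemble(
        learners=learners,
        fold_validation_scores=fold_scores,
        config=config,
        n_features=X.shape[1],
    )


def predict_map(ensemble: FittedEnsemble, scene: SpecimenScene):
    """Per-pixel mean-posterior cancer-probability map for a (TN) scene.

    Background pixels carry NaN; the returned map's ``valid`` mask marks
    tissue pixels that received a score.
    """
    from .evaluation import PredictionMap  # local import: no circular dep

    cube = scene.calibrated()
    if cube.grid.C != ensemble.n_features:
        raise ConfigurationError(
            f"scene has {cube.grid.C} bands; ensemble was trained on "
            f"{ensemble.n_features}"
        )
    tissue = scene.tissue_mask
    ys, xs = np.nonzero(tissue)
    scores = ensemble.posterior(cube.values[ys, xs, :])
    values = np.full(tissue.shape, np.nan)
    values[ys, xs] = scores
    return PredictionMap(values=values, valid=tissue.copy())
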