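"""Inter-patient patch-based CNN protocol.

Models that must generalize to unseen patients are trained with
patient-disjoint 5-fold cross-validation: all scenes of a patient share one
fold, each fold serves once as the fully-independent test group, and one of
the remaining folds is held out for validation (early stopping and
operating-point selection). Training uses primary-tumor (T) and all-normal
(N) specimens; testing is either on held-out patients' T/N specimens or on
their tumor-involved margin (TN) specimens.

Scenes are classified with a sliding window of 25 x 25 x C patches with a
13-pixel overlap (stride 12); per-patch cancer probabilities are averaged
over overlapping windows to reconstruct a smooth per-pixel heat map.

The classifier is a compact inception-style convolutional network (a 1x1
spectral-mixing stem followed by blocks with parallel 1x1/3x3/5x5 branches,
global average pooling, and a 2-way softmax), implemented in numpy with
explicit backpropagation — the same machinery that supplies the
class-activated gradients for spectral saliency. It accepts any band count
(3-band RGB, 23-band fluorescence, 91-band reflectance).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .evaluation import PredictionMap, optimal_operating_point, roc_auc
from .hypercube_io import TUMOR, ConfigurationError, SpecimenScene

__all__ = [
    "PatchSpec",
    "PatchSet",
    "FoldAssignment",
    "CNNConfig",
    "HeatMap",
    "SpectralInceptionNet",
    "TrainedModel",
    "ExperimentResult",
    "extract_patches",
    "assign_folds",
    "train_fold",
    "reconstruct_heatmap",
    "run_inter_patient_experiment",
]


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchSpec:
    """Sliding-window geometry: 25 px windows, 13 px overlap -> stride 12."""

    size_px: int = 25
    overlap_px: int = 13

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_px < self.size_px):
            raise ConfigurationError("overlap must satisfy 0 <= overlap < size")

    @property
    def stride_px(self) -> int:
        return self.size_px - self.overlap_px


@dataclass
class PatchSet:
    patches: np.ndarray  # m x size x size x C
    coords: np.ndarray  # m x 2 top-left (row, col)
    labels: np.ndarray  # m, patch class (1 = cancer), training only
    purity: np.ndarray  # m, tumor fraction of the patch's tissue pixels
    scene_ids: np.ndarray  # m, provenance
    patient_ids: np.ndarray  # m, provenance for the leakage audit

    def __len__(self) -> int:
        return len(self.coords)


def _lattice(extent: int, size: int, stride: int, flush: bool) -> np.ndarray:
    """Window offsets along one axis, plus a final flush window at the edge."""
    offsets = list(range(0, extent - size + 1, stride))
    if flush and offsets[-1] != extent - size:
        offsets.append(extent - size)
    return np.array(offsets)


def extract_patches(
    scene: SpecimenScene,
    spec: PatchSpec = PatchSpec(),
    mode: str = "inference",
    *,
    flush: bool = True,
    min_tissue_fraction: float = 0.5,
    drop_ambiguous_purity: tuple | None = None,
) -> PatchSet:
    """Extract sliding-window patches from a calibrated scene.

    Training mode keeps windows at least half covered by tissue and labels a
    patch cancerous when the tumor fraction of its tissue pixels is >= 0.5;
    ``drop_ambiguous_purity=(0.2, 0.8)`` optionally discards mixed patches.
    Inference mode keeps every window that touches tissue, so reconstruction
    covers the whole specimen.
    """
    cube = scene.calibrated()
    h, w, _ = cube.values.shape
    s = spec.size_px
    if h < s or w < s:
        raise ConfigurationError(f"image {h}x{w} smaller than patch size {s}")
    if mode not in ("training", "inference"):
        raise ConfigurationError(f"mode must be 'training' or 'inference', got {mode!r}")
    tissue = scene.tissue_mask
    tumor = scene.gt_mask == TUMOR
    rows = _lattice(h, s, spec.stride_px, flush)
    cols = _lattice(w, s, spec.stride_px, flush)

    patches, coords, labels, purity = [], [], [], []
    for r in rows:
        for c in cols:
            t_patch = tissue[r : r + s, c : c + s]
            n_tissue = int(t_patch.sum())
            if n_tissue == 0:
                continue
            frac_tissue = n_tissue / (s * s)
            pur = float(tumor[r : r + s, c : c + s][t_patch].mean())
            if mode == "training":
                if frac_tissue < min_tissue_fraction:
                    continue
                if drop_ambiguous_purity is not None:
                    lo, hi = drop_ambiguous_purity
                    if lo < pur < hi:
                        continue
            patches.append(cube.values[r : r + s, c : c + s, :])
            coords.append((r, c))
            labels.append(1 if pur >= 0.5 else 0)
            purity.append(pur)
    m = len(coords)
    scene_id = f"{scene.meta.patient_id}_{scene.meta.specimen_type}"
    return PatchSet(
        patches=np.asarray(patches, dtype=np.float32).reshape(m, s, s, cube.grid.C),
        coords=np.asarray(coords, dtype=int).reshape(m, 2),
        labels=np.asarray(labels, dtype=int),
        purity=np.asarray(purity, dtype=float),
        scene_ids=np.array([scene_id] * m),
        patient_ids=np.array([scene.meta.patient_id] * m),
    )


def concatenate_patchsets(sets: list[PatchSet]) -> PatchSet:
    sets = [s for s in sets if len(s)]
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        coords=np.concatenate([s.coords for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        purity=np.concatenate([s.purity for s in sets]),
        scene_ids=np.concatenate([s.scene_ids for s in sets]),
        patient_ids=np.concatenate([s.patient_ids for s in sets]),
    )


# ---------------------------------------------------------------------------
# Patient-level folds
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    fold_of_patient: dict
    k: int
    seed: int

    def patients_in_fold(self, fold: int) -> list:
        return sorted(p for p, f in self.fold_of_patient.items() if f == fold)


def assign_folds(patients, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Randomly split patients into k patient-disjoint folds of near-equal size."""
    patients = sorted(set(patients))
    if len(patients) < k:
        raise ConfigurationError(f"{len(patients)} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignment = {patients[i]: int(j % k) for j, i in enumerate(order)}
    return FoldAssignment(assignment, k, seed)


# ---------------------------------------------------------------------------
# Compact inception-style network (numpy, explicit backprop)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    stem_width: int = 16
    block_widths: tuple = (8, 8, 8)  # channels of the 1x1 / 3x3 / 5x5 branches
    n_blocks: int = 2
    epochs_max: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3  # decoupled; shrinks weights on uninformative bands
    patience: int = 5
    min_epochs: int = 1  # train at least this long before early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_max > 50:
            raise ConfigurationError("epochs_max capped at 50")
        if self.n_blocks < 1 or len(self.block_widths) != 3:
            raise ConfigurationError("need >= 1 block with three branch widths")


def _conv2d(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """'Same'-padded 2-D convolution, NHWC layout, odd kernel."""
    k = W.shape[0]
    p = k // 2
    if p:
        X = np.pad(X, ((0, 0), (p, p), (p, p), (0, 0)))
    m, hp, wp, cin = X.shape
    h, w = hp - 2 * p, wp - 2 * p
    s = X.strides
    cols = np.lib.stride_tricks.as_strided(
        X, (m, h, w, k, k, cin), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return np.tensordot(cols, W, axes=([3, 4, 5], [0, 1, 2]))


def _conv2d_backward(X: np.ndarray, W: np.ndarray, dY: np.ndarray):
    """Gradients of the same-padded convolution w.r.t. W, b, and X."""
    k = W.shape[0]
    p = k // 2
    Xp = np.pad(X, ((0, 0), (p, p), (p, p), (0, 0))) if p else X
    m, hp, wp, cin = Xp.shape
    h, w = hp - 2 * p, wp - 2 * p
    s = Xp.strides
    cols = np.lib.stride_tricks.as_strided(
        Xp, (m, h, w, k, k, cin), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    dW = np.tensordot(cols, dY, axes=([0, 1, 2], [0, 1, 2]))
    db = dY.sum(axis=(0, 1, 2))
    # dX is the correlation of dY with the spatially-flipped, channel-swapped kernel
    W_flip = W[::-1, ::-1].transpose(0, 1, 3, 2)
    dX = _conv2d(dY, W_flip)
    return dW, db, dX


class SpectralInceptionNet:
    """Small inception-style patch classifier for hypercube patches.

    Structure: 1x1 spectral-mixing stem -> ``n_blocks`` inception blocks
    (parallel 1x1, 3x3, 5x5 branches, concatenated, ReLU) -> global average
    pooling -> dense 2-way softmax. Spatial size is preserved throughout, so
    the network accepts the standard 25 x 25 x C patches for any C.
    """

    def __init__(self, n_bands: int, config: CNNConfig = CNNConfig()):
        self.config = config
        self.n_bands = n_bands
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        self.params["stem_W"] = he((1, 1, n_bands, config.stem_width), n_bands)
        self.params["stem_b"] = np.zeros(config.stem_width, np.float32)
        cin = config.stem_width
        self.block_out = int(sum(config.block_widths))
        for i in range(config.n_blocks):
            for branch, k in enumerate((1, 3, 5)):
                cout = config.block_widths[branch]
                self.params[f"b{i}_k{k}_W"] = he((k, k, cin, cout), k * k * cin)
                self.params[f"b{i}_k{k}_b"] = np.zeros(cout, np.float32)
            cin = self.block_out
        self.params["fc_W"] = he((cin, 2), cin)
        self.params["fc_b"] = np.zeros(2, np.float32)

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        """Logits and the cache of intermediate activations."""
        X = np.asarray(X, dtype=np.float32)
        cache: dict = {"X": X}
        a = _conv2d(X, self.params["stem_W"]) + self.params["stem_b"]
        cache["stem_pre"] = a
        a = np.maximum(a, 0)
        cache["stem_out"] = a
        for i in range(self.config.n_blocks):
            branches = []
            for k in (1, 3, 5):
                branches.append(
                    _conv2d(a, self.params[f"b{i}_k{k}_W"]) + self.params[f"b{i}_k{k}_b"]
                )
            pre = np.concatenate(branches, axis=-1)
            cache[f"block{i}_in"] = a
            cache[f"block{i}_pre"] = pre
            a = np.maximum(pre, 0)
            cache[f"block{i}_out"] = a
        g = a.mean(axis=(1, 2))
        cache["gap"] = g
        logits = g @ self.params["fc_W"] + self.params["fc_b"]
        return logits, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Cancer probability per patch, computed in batches."""
        out = np.empty(len(X))
        bs = self.config.batch_size
        for lo in range(0, len(X), bs):
            logits, _ = self.forward(X[lo : lo + bs])
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out[lo : lo + bs] = e[:, 1] / e.sum(axis=1)
        return out

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray, *, want_input_grad=False):
        """Backpropagate ``dlogits``; returns (param grads, extras).

        ``extras`` carries the gradient w.r.t. the last block's activations
        (for grad-CAM) and, if requested, w.r.t. the input patches.
        """
        grads: dict[str, np.ndarray] = {}
        g = cache["gap"]
        grads["fc_W"] = g.T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dg = dlogits @ self.params["fc_W"].T
        a = cache[f"block{self.config.n_blocks - 1}_out"]
        _, h, w, _ = a.shape
        da = np.broadcast_to(dg[:, None, None, :] / (h * w), a.shape).astype(np.float32)
        extras = {"last_block_grad": da.copy(), "last_block_act": a}
        for i in reversed(range(self.config.n_blocks)):
            pre = cache[f"block{i}_pre"]
            dpre = da * (pre > 0)
            x_in = cache[f"block{i}_in"]
            dx = np.zeros_like(x_in)
            c0 = 0
            for branch, k in enumerate((1, 3, 5)):
                cout = self.config.block_widths[branch]
                dY = dpre[..., c0 : c0 + cout]
                dW, db, dXb = _conv2d_backward(x_in, self.params[f"b{i}_k{k}_W"], dY)
                grads[f"b{i}_k{k}_W"] = dW
                grads[f"b{i}_k{k}_b"] = db
                dx += dXb
                c0 += cout
            da = dx
        dstem = da * (cache["stem_pre"] > 0)
        dW, db, dX = _conv2d_backward(cache["X"], self.params["stem_W"], dstem)
        grads["stem_W"] = dW
        grads["stem_b"] = db
        if want_input_grad:
            extras["input_grad"] = dX
        return grads, extras

    def class_gradients(self, X: np.ndarray, target_class: int):
        """Gradient of the target-class logit w.r.t. the last block's feature
        maps and the input patches (grad-CAM ingredients)."""
        logits, cache = self.forward(X)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        _, extras = self.backward(cache, dlogits, want_input_grad=True)
        return extras["last_block_act"], extras["last_block_grad"], extras["input_grad"]


@dataclass
class TrainedModel:
    net: SpectralInceptionNet
    history: list  # per-epoch validation AUC
    best_val_auc: float
    train_patient_ids: np.ndarray  # provenance for the leakage audit
    val_patient_ids: np.ndarray


def _softmax_ce_grad(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    loss = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(len(y)), y] -= 1.0
    return loss, dlogits / len(y)


def train_fold(
    train_set: PatchSet,
    val_set: PatchSet,
    config: CNNConfig = CNNConfig(),
) -> TrainedModel:
    """Train the patch classifier for one cross-validation fold.

    Per epoch, the majority class is randomly undersampled to balance the
    batch stream; Adam updates with early stopping on the validation AUC
    (parameters of the best epoch are restored).
    """
    y = train_set.labels
    if y.min() == y.max():
        raise ConfigurationError("training patches contain a single class only")
    net = SpectralInceptionNet(train_set.patches.shape[-1], config)
    rng = np.random.default_rng(config.seed)
    # Adam state
    m_state = {k: np.zeros_like(v, dtype=np.float64) for k, v in net.params.items()}
    v_state = {k: np.zeros_like(v, dtype=np.float64) for k, v in net.params.items()}
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    idx0 = np.nonzero(y == 0)[0]
    idx1 = np.nonzero(y == 1)[0]
    n_per_class = min(len(idx0), len(idx1))

    history = []
    best_auc, best_loss, best_params, since_best = -np.inf, np.inf, None, 0
    for _epoch in range(config.epochs_max):
        sel = np.concatenate(
            [
                rng.choice(idx0, n_per_class, replace=False),
                rng.choice(idx1, n_per_class, replace=False),
            ]
        )
        rng.shuffle(sel)
        for lo in range(0, len(sel), config.batch_size):
            batch = sel[lo : lo + config.batch_size]
            logits, cache = net.forward(train_set.patches[batch])
            _, dlogits = _softmax_ce_grad(logits, y[batch])
            grads, _ = net.backward(cache, dlogits)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, gval in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gval
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gval**2
                update = lr_t * m_state[k] / (np.sqrt(v_state[k]) + eps)
                if config.weight_decay and k.endswith("_W"):
                    update = update + config.learning_rate * config.weight_decay * net.params[k]
                net.params[k] = (net.params[k] - update).astype(np.float32)
        val_scores = net.predict_proba(val_set.patches)
        p = np.clip(np.where(val_set.labels == 1, val_scores, 1 - val_scores), 1e-12, None)
        val_loss = float(-np.log(p).mean())
        if val_set.labels.min() == val_set.labels.max():
            val_auc = float("nan")
        else:
            val_auc = roc_auc(val_scores, val_set.labels).auc
        history.append(val_auc)
        # AUC decides; validation loss breaks AUC ties so that continued
        # convergence at a saturated AUC still updates the kept parameters
        improved = np.isnan(val_auc) or val_auc > best_auc or (
            val_auc == best_auc and val_loss < best_loss
        )
        if improved:
            if not np.isnan(val_auc):
                best_auc = val_auc
            best_loss = min(best_loss, val_loss)
            best_params = copy.deepcopy(net.params)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience and _epoch + 1 >= config.min_epochs:
                break
    if best_params is not None:
        net.params = best_params
    return TrainedModel(
        net=net,
        history=history,
        best_val_auc=float(best_auc),
        train_patient_ids=np.unique(train_set.patient_ids),
        val_patient_ids=np.unique(val_set.patient_ids),
    )


# ---------------------------------------------------------------------------
# Heat-map reconstruction
# ---------------------------------------------------------------------------


@dataclass
class HeatMap:
    values: np.ndarray  # H x W in [0, 1]; NaN where no patch contributed
    coverage: np.ndarray  # H x W count of contributing patches


def reconstruct_heatmap(
    patch_scores: np.ndarray,
    coords: np.ndarray,
    image_shape: tuple,
    spec: PatchSpec = PatchSpec(),
) -> HeatMap:
    """Average overlapping patch scores into a per-pixel probability map.

    Every pixel's value is the exact mean of the scores of all patches that
    cover it; the coverage count is returned alongside.
    """
    h, w = image_shape
    s = spec.size_px
    total = np.zeros((h, w))
    count = np.zeros((h, w), dtype=int)
    for score, (r, c) in zip(np.asarray(patch_scores, dtype=float), coords):
        if r < 0 or c < 0 or r + s > h or c + s > w:
            raise ConfigurationError(f"patch at ({r}, {c}) lies outside {h}x{w} image")
        total[r : r + s, c : c + s] += score
        count[r : r + s, c : c + s] += 1
    values = np.full((h, w), np.nan)
    covered = count > 0
    values[covered] = total[covered] / count[covered]
    return HeatMap(values=values, coverage=count)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    experiment: str
    folds: FoldAssignment
    predictions: dict  # (patient_id, specimen_type) -> PredictionMap
    thresholds: dict  # fold -> validation operating-point threshold
    fold_of_scene: dict  # (patient_id, specimen_type) -> test fold
    train_patients_of_fold: dict  # fold -> patient ids used for training
    val_auc_of_fold: dict  # fold -> validation AUC of the trained model
    models: dict  # fold -> TrainedModel


def run_inter_patient_experiment(
    scenes: dict,
    experiment: str = "TvsN",
    config: CNNConfig = CNNConfig(),
    patch_spec: PatchSpec = PatchSpec(),
    *,
    k: int = 5,
    seed: int = 0,
) -> ExperimentResult:
    """Patient-level k-fold cross-validated patch-CNN experiment.

    ``scenes`` maps ``(patient_id, specimen_type)`` to a
    :class:`SpecimenScene` (as produced by the phantom cohort generator).
    For each fold: models train on T and N scenes of the non-test,
    non-validation patients, the validation fold supplies early stopping and
    the operating point, and predictions are made once per test scene —
    on T and N scenes (``experiment="TvsN"``), on TN margin scenes
    (``experiment="TN"``), or on all three (``experiment="both"``, one
    training pass serving both tests). No test patient contributes a single
    pixel to the model that scores it.
    """
    if experiment not in ("TvsN", "TN", "both"):
        raise ConfigurationError("experiment must be 'TvsN', 'TN', or 'both'")
    patients = sorted({pid for pid, _ in scenes})
    folds = assign_folds(patients, k=k, seed=seed)

    predictions: dict = {}
    thresholds: dict = {}
    fold_of_scene: dict = {}
    train_patients_of_fold: dict = {}
    val_auc_of_fold: dict = {}
    models: dict = {}

    def training_patchsets(pids):
        sets = []
        for pid in pids:
            for stype in ("T", "N"):
                if (pid, stype) in scenes:
                    sets.append(
                        extract_patches(scenes[(pid, stype)], patch_spec, "training")
                    )
        return concatenate_patchsets(sets)

    for fold in range(k):
        test_pids = folds.patients_in_fold(fold)
        val_fold = (fold + 1) % k
        val_pids = folds.patients_in_fold(val_fold)
        train_pids = [
            p for p in patients if folds.fold_of_patient[p] not in (fold, val_fold)
        ]
        train_set = training_patchsets(train_pids)
        val_set = training_patchsets(val_pids)
        fold_config = CNNConfig(
            **{
                **{f: getattr(config, f) for f in config.__dataclass_fields__},
                "seed": (config.seed * 1000 + fold) & 0x7FFFFFFF,
            }
        )
        model = train_fold(train_set, val_set, fold_config)
        models[fold] = model
        train_patients_of_fold[fold] = list(train_pids)
        val_auc_of_fold[fold] = model.best_val_auc
        val_scores = model.net.predict_proba(val_set.patches)
        thresholds[fold] = optimal_operating_point(
            roc_auc(val_scores, val_set.labels), source=f"fold{val_fold}"
        ).threshold

        test_types = {"TvsN": ("T", "N"), "TN": ("TN",), "both": ("T", "N", "TN")}[
            experiment
        ]
        for pid in test_pids:
            for stype in test_types:
                if (pid, stype) not in scenes:
                    continue
                scene = scenes[(pid, stype)]
                pset = extract_patches(scene, patch_spec, "inference")
                scores = model.net.predict_proba(pset.patches)
                heat = reconstruct_heatmap(
                    scores, pset.coords, scene.gt_mask.shape, patch_spec
                )
                valid = (heat.coverage > 0) & scene.tissue_mask
                values = np.where(valid, heat.values, np.nan)
                predictions[(pid, stype)] = PredictionMap(values=values, valid=valid)
                fold_of_scene[(pid, stype)] = fold

    return ExperimentResult(
        experiment=experiment,
        folds=folds,
        predictions=predictions,
        thresholds=thresholds,
        fold_of_scene=fold_of_scene,
        train_patients_of_fold=train_patients_of_fold,
        val_auc_of_fold=val_auc_of_fold,
        models=models,
    )
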