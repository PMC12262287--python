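"""Per-nucleus amplification classification and sample-level aggregation.

Three classification routes are provided: a deterministic heuristic on
image-level copy-number statistics (mean/variance cut-offs), a trainable
patch classifier harness, and a focal/no-focal gate combiner that folds
a centromere-informed binary call into the three-class target call.
Per-cell hard labels are aggregated into a sample call by bootstrapped
10-cell majority votes and fixed fraction thresholds; heterogeneity
between samples is compared with a Pearson chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging_core import NucleusPatch

CLASSES = ("EC-amp", "HSR-amp", "no-amp")


@dataclass
class NucleusPrediction:
    """Per-nucleus class posteriors over (EC-amp, HSR-amp, no-amp)."""

    nucleus_id: int
    posteriors: np.ndarray
    source: str = "heuristic"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.min() < 0 or abs(self.posteriors.sum() - 1) > 1e-6:
            raise ValueError("posteriors must be non-negative and sum to 1")

    @property
    def hard_label(self) -> str:
        return CLASSES[int(np.argmax(self.posteriors))]


@dataclass
class HeuristicThresholds:
    """Copy-number-statistic cut-offs separating HSR-like from EC-like
    images: HSR-amp images typically have mean < 10 and variance < 64."""

    mean_cut: float = 10.0
    var_cut: float = 64.0

    def __post_init__(self) -> None:
        if self.mean_cut <= 0 or self.var_cut <= 0:
            raise ValueError("thresholds must be positive")


def heuristic_classify(
    image_stats: tuple[float, float],
    thresholds: HeuristicThresholds | None = None,
) -> str:
    """HSR-like iff mean < mean_cut and variance < var_cut (strict), else
    EC-like; ``image_stats`` is the (mean, variance) of the per-nucleus
    copy number signal of one image."""
    thresholds = thresholds or HeuristicThresholds()
    mean, variance = image_stats
    if mean < thresholds.mean_cut and variance < thresholds.var_cut:
        return "HSR-like"
    return "EC-like"


def threshold_grid_search(
    image_stats: list[tuple[float, float]],
    truth_labels: list[str],
    mean_grid: list[float],
    var_grid: list[float],
) -> tuple[HeuristicThresholds, float]:
    """Exhaustive accuracy maximization over (mean_cut, var_cut) pairs.

    ``truth_labels`` use 'HSR-like'/'EC-like'.  Ties are broken by the
    smallest (mean_cut, var_cut).
    """
    if not mean_grid or not var_grid:
        raise ValueError("empty threshold grid")
    if len(set(truth_labels)) < 2:
        raise ValueError("grid search needs at least two classes present")
    best = None
    for m in sorted(mean_grid):
        for v in sorted(var_grid):
            thr = HeuristicThresholds(mean_cut=m, var_cut=v)
            correct = sum(
                heuristic_classify(s, thr) == lab
                for s, lab in zip(image_stats, truth_labels)
            )
            acc = correct / len(truth_labels)
            if best is None or acc > best[1]:
                best = (thr, acc)
    return best


# ---------------------------------------------------------------------------
# Trainable patch-classifier harness
# ---------------------------------------------------------------------------


@dataclass
class CnnConfig:
    """Configuration of the patch classifier and its training loop.

    ``dense_blocks`` and ``growth_factor`` size the network (hidden layer
    widths are block * growth_factor); the reference full-scale
    configuration is blocks (6, 12, 24, 16) with growth factor 32.
    Learning rate defaults to 1e-4 for the three-class model and 5e-4
    for the binary model.  Early stopping uses a patience of 7 epochs on
    validation loss (three-class) or validation AUC (binary);
    ``balanced_sampling`` draws each epoch's examples with equal total
    weight per stratum.  ``init_weights`` accepts externally supplied
    parameters; default is seeded random initialization.
    """

    n_classes: int = 3
    dense_blocks: tuple[int, ...] = (6, 12, 24, 16)
    growth_factor: int = 32
    learning_rate: float | None = None
    patience: int = 7
    max_epochs: int = 200
    balanced_sampling: bool = False
    seed: int = 0
    feature_pool: int = 16
    init_weights: list | None = None

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.patience < 1 or self.max_epochs < 1 or self.growth_factor < 1:
            raise ValueError("config values must be positive")
        if self.learning_rate is None:
            self.learning_rate = 1e-4 if self.n_classes == 3 else 5e-4


def _patch_features(patch: NucleusPatch | np.ndarray, pool: int) -> np.ndarray:
    """Block-mean downsample each channel to pool x pool and flatten."""
    px = patch.pixels if isinstance(patch, NucleusPatch) else np.asarray(patch)
    if px.ndim == 2:
        px = px[:, :, None]
    px = px.astype(float)
    if px.dtype != float or px.max() > 1.5:
        px = px / 255.0
    h, w, c = px.shape
    bh, bw = h // pool, w // pool
    px = px[: bh * pool, : bw * pool]
    feat = px.reshape(pool, bh, pool, bw, c).mean(axis=(1, 3))
    return feat.ravel()


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class PatchClassifier:
    """Feed-forward softmax network trained with Adam and early stopping.

    A compact, fully connected stand-in sized by :class:`CnnConfig`:
    each entry of ``dense_blocks`` contributes one ReLU hidden layer of
    width block * growth_factor over block-pooled patch features.
    """

    def __init__(self, config: CnnConfig, n_features: int):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = [n_features] + [
            b * config.growth_factor for b in config.dense_blocks
        ] + [config.n_classes]
        if config.init_weights is not None:
            self.weights = [(np.array(W), np.array(b)) for W, b in config.init_weights]
        else:
            self.weights = [
                (
                    rng.normal(0, np.sqrt(2 / widths[i]), (widths[i], widths[i + 1])),
                    np.zeros(widths[i + 1]),
                )
                for i in range(len(widths) - 1)
            ]
        self.classes_: list[str] = []

    def _forward(self, X: np.ndarray):
        acts = [X]
        a = X
        for i, (W, b) in enumerate(self.weights):
            z = a @ W + b
            a = z if i == len(self.weights) - 1 else np.maximum(z, 0)
            acts.append(a)
        return _softmax(acts[-1]), acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(X))[0]

    def _gradients(self, acts: list[np.ndarray], probs: np.ndarray, onehot: np.ndarray):
        grads = []
        delta = (probs - onehot) / len(onehot)
        for i in range(len(self.weights) - 1, -1, -1):
            W, _ = self.weights[i]
            grads.append((acts[i].T @ delta, delta.sum(axis=0)))
            if i > 0:
                delta = (delta @ W.T) * (acts[i] > 0)
        return grads[::-1]


def _auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC of scores for the positive class (class index 1)."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        return 0.5
    order = stats.rankdata(np.concatenate([neg, pos]))
    return (order[len(neg):].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )


def _balanced_epoch_indices(
    strata: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n indices with equal total sampling weight per stratum."""
    groups = {}
    for i, s in enumerate(strata):
        groups.setdefault(s, []).append(i)
    keys = sorted(groups)
    weights = np.zeros(len(strata))
    for k in keys:
        weights[groups[k]] = 1.0 / (len(keys) * len(groups[k]))
    return rng.choice(len(strata), size=n, replace=True, p=weights)


def cnn_train(
    patches: list,
    labels: list[str],
    config: CnnConfig | None = None,
    validation: tuple[list, list[str]] | None = None,
    strata: list | None = None,
) -> PatchClassifier:
    """Train the patch classifier with cross-entropy, Adam, and patience-
    based early stopping.

    Three-class mode stops on validation loss; binary mode stops on
    validation AUC.  With ``balanced_sampling`` each epoch draws
    ``len(patches)`` examples with replacement at equal total weight per
    stratum (default strata: the labels themselves; pass explicit
    ``strata`` for e.g. tissue-type x amplification-type pairs).  When no
    validation split is given the training metric is used.  Returns the
    trained classifier with the best-scoring weights restored.
    """
    config = config or CnnConfig()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if len(classes) > config.n_classes:
        raise ValueError("more label classes than config.n_classes")
    rng = np.random.default_rng(config.seed + 1)
    X = np.stack([_patch_features(p, config.feature_pool) for p in patches])
    y = np.array([classes.index(l) for l in labels])
    onehot = np.eye(config.n_classes)[y]
    if validation is not None:
        Xv = np.stack([_patch_features(p, config.feature_pool) for p in validation[0]])
        yv = np.array([classes.index(l) for l in validation[1]])
    else:
        Xv, yv = X, y

    model = PatchClassifier(config, X.shape[1])
    model.classes_ = classes
    strata_arr = np.array(strata if strata is not None else labels)

    # Adam state
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_score, best_weights, since_best = np.inf, None, 0
    t = 0
    for epoch in range(config.max_epochs):
        if config.balanced_sampling:
            idx = _balanced_epoch_indices(strata_arr, len(X), rng)
        else:
            idx = rng.permutation(len(X))
        probs, acts = model._forward(X[idx])
        grads = model._gradients(acts, probs, onehot[idx])
        t += 1
        for i, ((gW, gb), (W, b)) in enumerate(zip(grads, model.weights)):
            mW = beta1 * m[i][0] + (1 - beta1) * gW
            mb = beta1 * m[i][1] + (1 - beta1) * gb
            vW = beta2 * v[i][0] + (1 - beta2) * gW**2
            vb = beta2 * v[i][1] + (1 - beta2) * gb**2
            m[i], v[i] = (mW, mb), (vW, vb)
            mWh, mbh = mW / (1 - beta1**t), mb / (1 - beta1**t)
            vWh, vbh = vW / (1 - beta2**t), vb / (1 - beta2**t)
            model.weights[i] = (
                W - config.learning_rate * mWh / (np.sqrt(vWh) + eps),
                b - config.learning_rate * mbh / (np.sqrt(vbh) + eps),
            )
        val_probs = model.predict_proba(Xv)
        if config.n_classes == 2:
            score = -_auc(yv, val_probs[:, 1])  # maximize AUC
        else:
            score = -np.log(
                np.clip(val_probs[np.arange(len(yv)), yv], 1e-12, None)
            ).mean()
        if score < best_score - 1e-9:
            best_score = score
            best_weights = [(W.copy(), b.copy()) for W, b in model.weights]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_weights is not None:
        model.weights = best_weights
    return model


def cnn_predict(
    model: PatchClassifier, patches: list, nucleus_ids: list[int] | None = None
) -> list[NucleusPrediction]:
    """Posteriors and argmax hard labels for a list of patches."""
    X = np.stack([_patch_features(p, model.config.feature_pool) for p in patches])
    if X.shape[1] != model.weights[0][0].shape[0]:
        raise ValueError("patch channel/feature layout differs from training")
    probs = model.predict_proba(X)
    preds = []
    for i, p in enumerate(probs):
        full = np.zeros(len(CLASSES))
        for j, cls in enumerate(model.classes_):
            full[CLASSES.index(cls)] = p[j]
        full = full / full.sum()
        preds.append(
            NucleusPrediction(
                nucleus_id=nucleus_ids[i] if nucleus_ids else i,
                posteriors=full,
                source="cnn",
            )
        )
    return preds


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def combine_focal_gate(
    target_only_pred: NucleusPrediction, focal_pred: str | None
) -> NucleusPrediction:
    """Fold a centromere-informed focal/no-focal call into the target call.

    ``no-focal-amp`` forces the final label to no-amp; ``focal-amp``
    picks the better of EC-amp/HSR-amp from the target-only posteriors;
    an absent gate (centromeric QC failed) passes the target-only
    prediction through unchanged.
    """
    if focal_pred is None:
        return target_only_pred
    if focal_pred == "no-focal-amp":
        post = np.array([0.0, 0.0, 1.0])
    elif focal_pred == "focal-amp":
        ec, hsr = target_only_pred.posteriors[0], target_only_pred.posteriors[1]
        post = np.array([1.0, 0.0, 0.0]) if ec >= hsr else np.array([0.0, 1.0, 0.0])
    else:
        raise ValueError(f"unknown focal gate value: {focal_pred}")
    return NucleusPrediction(
        nucleus_id=target_only_pred.nucleus_id, posteriors=post, source="focal_gate"
    )


def merge_window_predictions(
    predictions: list[NucleusPrediction],
) -> list[NucleusPrediction]:
    """Merge per-window predictions of sliding-window nuclei into one
    prediction per nucleus by mean posterior."""
    by_nucleus: dict[int, list[NucleusPrediction]] = {}
    for p in predictions:
        by_nucleus.setdefault(p.nucleus_id, []).append(p)
    merged = []
    for nid in sorted(by_nucleus):
        post = np.mean([p.posteriors for p in by_nucleus[nid]], axis=0)
        merged.append(
            NucleusPrediction(
                nucleus_id=nid, posteriors=post / post.sum(),
                source=by_nucleus[nid][0].source,
            )
        )
    return merged


@dataclass
class BootstrapConfig:
    """10-cell majority votes repeated 100 times, by default."""

    cells_per_draw: int = 10
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_draw < 1 or self.n_iterations < 1:
            raise ValueError("bootstrap sizes must be positive")


def bootstrap_sample_call(
    hard_labels: list[str], config: BootstrapConfig | None = None
) -> dict[str, float]:
    """Distribution of majority-vote winners over bootstrap draws.

    Each iteration draws ``cells_per_draw`` cells uniformly with
    replacement and records the modal label, breaking ties uniformly at
    random under the iteration's RNG stream; the returned mapping gives
    the fraction of iterations each class won.
    """
    if len(hard_labels) == 0:
        raise ValueError("need at least one prediction")
    config = config or BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    labels = np.asarray(hard_labels)
    wins = dict.fromkeys(CLASSES, 0)
    for lab in labels:
        if lab not in wins:
            wins[lab] = 0
    for _ in range(config.n_iterations):
        draw = labels[rng.integers(0, len(labels), size=config.cells_per_draw)]
        values, counts = np.unique(draw, return_counts=True)
        tied = values[counts == counts.max()]
        winner = tied[0] if len(tied) == 1 else tied[rng.integers(len(tied))]
        wins[str(winner)] += 1
    return {k: v / config.n_iterations for k, v in wins.items()}


@dataclass
class SampleRule:
    """Fraction thresholds converting per-cell calls to one sample call."""

    noamp_cut: float = 0.80
    hsr_cut: float = 0.80
    ec_cut: float = 0.50

    def __post_init__(self) -> None:
        for v in (self.noamp_cut, self.hsr_cut, self.ec_cut):
            if not 0 < v <= 1:
                raise ValueError("cuts must lie in (0, 1]")


def sample_rule_call(
    label_fractions: dict[str, float], rule: SampleRule | None = None
) -> str:
    """Sample-level call: no-amp if >= 80% of cells are no-amp, HSR-amp
    if >= 80% are HSR-amp, EC-amp if >= 50% are EC-amp, else
    heterogeneous.  Thresholds apply in that order."""
    rule = rule or SampleRule()
    total = sum(label_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("label fractions must sum to 1")
    if label_fractions.get("no-amp", 0.0) >= rule.noamp_cut:
        return "no-amp"
    if label_fractions.get("HSR-amp", 0.0) >= rule.hsr_cut:
        return "HSR-amp"
    if label_fractions.get("EC-amp", 0.0) >= rule.ec_cut:
        return "EC-amp"
    return "heterogeneous"


def heterogeneity_chisq(
    counts_a: dict[str, int] | list[int], counts_b: dict[str, int] | list[int]
) -> tuple[float, int, float]:
    """Pearson chi-square comparison of two per-class count vectors.

    Classes with zero counts in both samples are dropped before the df
    computation (df = retained classes - 1).  Returns
    (statistic, df, p_value).
    """
    if isinstance(counts_a, dict):
        keys = sorted(set(counts_a) | set(counts_b))
        a = np.array([counts_a.get(k, 0) for k in keys], dtype=float)
        b = np.array([counts_b.get(k, 0) for k in keys], dtype=float)
    else:
        a, b = np.asarray(counts_a, dtype=float), np.asarray(counts_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("count vectors must share the class index set")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a sample has all-zero counts")
    if len(a) < 2:
        raise ValueError("need at least two retained classes")
    stat, p, df, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(stat), int(df), float(p)
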