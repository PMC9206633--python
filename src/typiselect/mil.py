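"""Attention-based multiple-instance learning for slide-level subtype prediction.

A slide is represented by *bags* of image patches sampled from its tissue
region.  Each patch is encoded to a Q-dimensional feature ``h``; a small
attention network assigns each patch a weight ``a_i`` (softmax-normalized
within the bag), the bag feature is the weighted sum ``z = sum_i a_i h_i``,
and a softmax classifier maps ``z`` to bag-level class probabilities.  The
model is trained by minimizing the bag-level cross-entropy; the slide-level
probability pools bag probabilities by a normalized geometric mean:

    p_k  proportional to  exp( mean_b log P(Y_b = k) ).

The network here is a compact fully-vectorized numpy implementation: the
patch encoder mean-pools each patch to a small color grid and applies a
one-hidden-layer tanh MLP; the attention net is a two-layer tanh scorer.
Presets: ``"tiny"`` (32x32 patches, Q=32; the default and the one exercised
by the test suite) and ``"paper-scale"`` (224x224 patches, Q=512) which runs
the same pathway at the larger geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import gaussian, threshold_otsu
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "Patch",
    "Bag",
    "MILConfig",
    "AttentionMILClassifier",
    "detect_tissue",
    "extract_patches",
    "make_bags",
    "bag_loss",
    "aggregate_slide",
    "evaluate_model",
    "attention_heatmap",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Patch:
    """One P×P RGB tile and its top-left location in slide coordinates."""

    pixels: np.ndarray
    slide_id: str
    location: tuple[int, int]


@dataclass
class Bag:
    """Fixed-size set of patches from one slide, labeled with its subtype."""

    bag_id: str
    slide_id: str
    patches: list[Patch]
    label: int | None = None


@dataclass
class MILConfig:
    """Architecture and optimization settings.

    ``pool_grid`` is the side of the color grid each patch is mean-pooled to
    before the encoder MLP (so the encoder input has ``3 * pool_grid**2``
    features regardless of patch size).
    """

    patch_size: int = 32
    feature_dim: int = 32  # Q
    pool_grid: int = 4
    attention_hidden: int = 16
    n_classes: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 4
    n_epochs: int = 12
    n_bags: int = 4
    bag_size: int = 25
    max_patches: int = 5000
    min_tissue_fraction: float = 0.5
    preset: str = "tiny"

    @classmethod
    def tiny(cls, **kw) -> "MILConfig":
        return cls(preset="tiny", **kw)

    @classmethod
    def paper_scale(cls, **kw) -> "MILConfig":
        """Large-geometry preset: 224px patches, Q=512, 50 bags of 100."""
        defaults = dict(
            patch_size=224,
            feature_dim=512,
            pool_grid=8,
            attention_hidden=128,
            n_bags=50,
            bag_size=100,
            preset="paper-scale",
        )
        defaults.update(kw)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# tissue detection and patch/bag construction
# ---------------------------------------------------------------------------


def detect_tissue(slide_image: np.ndarray) -> np.ndarray:
    """Binary tissue mask: saturation above an Otsu threshold after light blur.

    Stained tissue is colorful against the near-white glass background, so
    the HSV saturation channel separates the two; a small Gaussian blur
    suppresses pixel noise before thresholding.  The automatic threshold is
    capped at 0.1 saturation: when strongly and weakly stained tissue form
    the two dominant modes, an uncapped Otsu split would discard the weakly
    stained tissue, while glass sits well below 0.1 saturation.
    """
    img = np.asarray(slide_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    sat = rgb2hsv(img)[..., 1]
    sat = gaussian(sat, sigma=1)
    if sat.max() - sat.min() < 1e-6:
        logger.warning("blank image: empty tissue mask")
        return np.zeros(sat.shape, dtype=bool)
    thr = min(threshold_otsu(sat), 0.1)
    mask = sat > thr
    logger.debug("tissue fraction %.3f", mask.mean())
    return mask


def extract_patches(
    slide: np.ndarray,
    mask: np.ndarray,
    patch_size: int,
    max_patches: int = 5000,
    min_tissue_fraction: float = 0.5,
    seed: int = 0,
    slide_id: str = "slide",
) -> list[Patch]:
    """Randomly sample tissue patches from the non-overlapping grid.

    Grid positions whose tissue fraction is at least ``min_tissue_fraction``
    are eligible; at most ``max_patches`` are drawn uniformly without
    replacement.  Deterministic given ``seed``.
    """
    H, W = mask.shape
    P = patch_size
    if P > H or P > W:
        raise ValueError("patch does not fit in slide")
    rng = np.random.default_rng(seed)
    positions = [
        (r, c)
        for r in range(0, H - P + 1, P)
        for c in range(0, W - P + 1, P)
        if mask[r : r + P, c : c + P].mean() >= min_tissue_fraction
    ]
    if not positions:
        raise ValueError("no grid position meets the tissue-fraction threshold")
    if len(positions) > max_patches:
        sel = rng.choice(len(positions), size=max_patches, replace=False)
        positions = [positions[i] for i in sorted(sel)]
    return [
        Patch(pixels=slide[r : r + P, c : c + P], slide_id=slide_id, location=(r, c))
        for r, c in positions
    ]


def make_bags(
    patches: list[Patch],
    n_bags: int = 50,
    bag_size: int = 100,
    seed: int = 0,
    label: int | None = None,
) -> list[Bag]:
    """Group patches into ``n_bags`` bags of ``bag_size``.

    With enough patches the bags are a random partition (each patch used at
    most once); otherwise each bag is drawn without replacement so bags may
    share patches but never repeat one internally.
    """
    if len(patches) < bag_size:
        raise ValueError(f"{len(patches)} patches < bag_size={bag_size}")
    rng = np.random.default_rng(seed)
    sid = patches[0].slide_id
    bags = []
    if len(patches) >= n_bags * bag_size:
        perm = rng.permutation(len(patches))
        for b in range(n_bags):
            idx = perm[b * bag_size : (b + 1) * bag_size]
            bags.append(Bag(f"{sid}#b{b}", sid, [patches[i] for i in idx], label))
    else:
        for b in range(n_bags):
            idx = rng.choice(len(patches), size=bag_size, replace=False)
            bags.append(Bag(f"{sid}#b{b}", sid, [patches[i] for i in idx], label))
    return bags


# ---------------------------------------------------------------------------
# slide-level aggregation and metrics
# ---------------------------------------------------------------------------


def bag_loss(probabilities: np.ndarray, label: int | np.ndarray) -> float:
    """Bag-level cross-entropy: mean of -log P(true class) over a minibatch."""
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y = np.atleast_1d(np.asarray(label, dtype=int))
    p_true = np.clip(P[np.arange(len(y)), y], _EPS, None)
    return float(-np.mean(np.log(p_true)))


def aggregate_slide(bag_probabilities: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Slide probability as the normalized geometric mean of bag probabilities.

    ``p_k = exp(mean_b log P(Y_b = k))`` normalized to sum 1; probabilities
    are clamped at 1e-12 before the log.  Invariant to bag order.
    """
    P = np.atleast_2d(np.asarray(bag_probabilities, dtype=float))
    if P.size == 0:
        raise ValueError("need at least one bag")
    logp = np.log(np.clip(P, _EPS, None)).mean(axis=0)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def evaluate_model(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int):
    """Accuracy, macro-F1 and the confusion matrix (rows = true class).

    Macro-F1 is the unweighted mean of per-class F1 scores; a class absent
    from both truth and prediction contributes an F1 of 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    acc = float(np.trace(cm) / max(cm.sum(), 1))
    f1s = []
    for k in range(n_classes):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        f1s.append(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))
    return acc, float(np.mean(f1s)), cm


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


def _pool_features(patches: list[Patch], grid: int) -> np.ndarray:
    """Mean-pool each patch to a grid×grid×3 color summary in [0, 1]."""
    P = patches[0].pixels.shape[0]
    X = np.stack([p.pixels for p in patches]).astype(np.float64) / 255.0
    g = grid
    s = P // g
    X = X[:, : g * s, : g * s, :]
    X = X.reshape(len(patches), g, s, g, s, 3).mean(axis=(2, 4))
    return X.reshape(len(patches), -1)


@dataclass
class _Params:
    W1: np.ndarray
    b1: np.ndarray
    Wa1: np.ndarray
    ba1: np.ndarray
    wa2: np.ndarray
    ba2: float
    Wc: np.ndarray
    bc: np.ndarray

    def copy(self) -> "_Params":
        return _Params(*(np.copy(v) if isinstance(v, np.ndarray) else v for v in vars(self).values()))


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Bag-of-patches subtype classifier with learned patch attention.

    ``fit`` consumes slides (image + tissue mask + label); per epoch it
    resamples patches and bags from the training slides, runs one Adam pass
    over the bags, records the validation bag loss, and finally restores the
    parameters of the epoch with the smallest validation loss (earliest on
    ties).  ``predict`` aggregates per-bag probabilities to a slide label.

    Parameters
    ----------
    config : MILConfig, optional
        Architecture/optimization settings (default: the tiny preset).
    random_state : int, default=0
        Seeds parameter init and all patch/bag sampling.

    Attributes
    ----------
    params_ : fitted network parameters (selected checkpoint)
    validation_losses_ : per-epoch mean validation bag loss
    selected_epoch_ : int, 1-based epoch of the restored checkpoint
    classes_ : ndarray of class labels
    """

    def __init__(self, config: MILConfig | None = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    # -- forward / backward ------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> _Params:
        cfg = self._cfg
        d_in = 3 * cfg.pool_grid**2
        sc = lambda a, b: np.sqrt(2.0 / (a + b))
        return _Params(
            W1=rng.normal(0, sc(d_in, cfg.feature_dim), (d_in, cfg.feature_dim)),
            b1=np.zeros(cfg.feature_dim),
            Wa1=rng.normal(0, sc(cfg.feature_dim, cfg.attention_hidden), (cfg.feature_dim, cfg.attention_hidden)),
            ba1=np.zeros(cfg.attention_hidden),
            wa2=rng.normal(0, sc(cfg.attention_hidden, 1), cfg.attention_hidden),
            ba2=0.0,
            Wc=rng.normal(0, sc(cfg.feature_dim, cfg.n_classes), (cfg.feature_dim, cfg.n_classes)),
            bc=np.zeros(cfg.n_classes),
        )

    def _forward(self, F: np.ndarray, params: _Params | None = None):
        """Forward one bag: F is (n_patches, d_in). Returns (probs, attention, cache)."""
        p = params or self.params_
        H = np.tanh(F @ p.W1 + p.b1)
        V = np.tanh(H @ p.Wa1 + p.ba1)
        s = V @ p.wa2 + p.ba2
        s = s - s.max()
        a = np.exp(s)
        a = a / a.sum()
        z = a @ H
        logits = z @ p.Wc + p.bc
        logits = logits - logits.max()
        probs = np.exp(logits)
        probs = probs / probs.sum()
        return probs, a, (F, H, V, a, z, probs)

    def _backward(self, cache, y: int, p: _Params) -> _Params:
        F, H, V, a, z, probs = cache
        dlogits = probs.copy()
        dlogits[y] -= 1.0
        gWc = np.outer(z, dlogits)
        gbc = dlogits
        dz = p.Wc @ dlogits
        dH = np.outer(a, dz)
        da = H @ dz
        ds = a * (da - float(a @ da))
        dV = np.outer(ds, p.wa2)
        gwa2 = V.T @ ds
        gba2 = float(ds.sum())
        dpreV = dV * (1 - V**2)
        gWa1 = H.T @ dpreV
        gba1 = dpreV.sum(axis=0)
        dH += dpreV @ p.Wa1.T
        dpreH = dH * (1 - H**2)
        gW1 = F.T @ dpreH
        gb1 = dpreH.sum(axis=0)
        return _Params(gW1, gb1, gWa1, gba1, gwa2, gba2, gWc, gbc)

    # -- estimator API -----------------------------------------------------

    def fit(self, slides: dict, y=None) -> "AttentionMILClassifier":
        """Train on a slide collection.

        ``slides`` maps slide_id -> dict(image=..., mask=..., label=int,
        split='train'|'validation').  Masks default to ``detect_tissue``.
        """
        self._cfg = self.config or MILConfig.tiny()
        cfg = self._cfg
        if cfg.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        train_ids = [s for s, d in slides.items() if d.get("split", "train") == "train"]
        val_ids = [s for s, d in slides.items() if d.get("split") == "validation"]
        if not train_ids or not val_ids:
            raise ValueError("need nonempty train and validation slide sets")
        self.classes_ = np.unique([slides[s]["label"] for s in slides])
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng)
        adam_m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in vars(params).items()}
        adam_v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in vars(params).items()}
        t_step = 0

        def slide_features(sid: str, epoch_seed: int) -> list[np.ndarray]:
            d = slides[sid]
            mask = d.get("mask")
            if mask is None:
                mask = detect_tissue(d["image"])
            patches = extract_patches(
                d["image"], np.asarray(mask, dtype=bool), cfg.patch_size,
                cfg.max_patches, cfg.min_tissue_fraction, seed=epoch_seed, slide_id=sid,
            )
            bag_size = min(cfg.bag_size, len(patches))
            bags = make_bags(patches, cfg.n_bags, bag_size, seed=epoch_seed + 1, label=d["label"])
            return [(_pool_features(b.patches, cfg.pool_grid), d["label"]) for b in bags]

        # validation bags fixed once for a stable model-selection signal
        val_seed = int(rng.integers(2**31 - 1))
        val_bags = [fb for sid in val_ids for fb in slide_features(sid, val_seed)]

        self.validation_losses_ = []
        best = (np.inf, 0, params.copy())
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for epoch in range(1, cfg.n_epochs + 1):
            ep_seed = int(rng.integers(2**31 - 1))
            train_bags = [fb for sid in train_ids for fb in slide_features(sid, ep_seed)]
            order = rng.permutation(len(train_bags))
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                grads = None
                for i in batch:
                    F, yb = train_bags[i]
                    probs, _, cache = self._forward(F, params)
                    if not np.all(np.isfinite(probs)):
                        raise FloatingPointError("non-finite bag probabilities during training")
                    g = self._backward(cache, int(yb), params)
                    if grads is None:
                        grads = g
                    else:
                        for k in vars(grads):
                            setattr(grads, k, getattr(grads, k) + getattr(g, k))
                t_step += 1
                for k in vars(params):
                    gk = np.asarray(getattr(grads, k), dtype=float) / len(batch)
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * gk
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * gk**2
                    mhat = adam_m[k] / (1 - beta1**t_step)
                    vhat = adam_v[k] / (1 - beta2**t_step)
                    upd = cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    cur = getattr(params, k)
                    setattr(params, k, cur - upd if isinstance(cur, np.ndarray) else float(cur - upd))
            val_loss = float(
                np.mean([bag_loss(self._forward(F, params)[0], yb) for F, yb in val_bags])
            )
            if not np.isfinite(val_loss):
                raise FloatingPointError("validation loss diverged")
            self.validation_losses_.append(val_loss)
            if val_loss < best[0] - 1e-12:
                best = (val_loss, epoch, params.copy())
            logger.debug("epoch %d: val bag loss %.4f", epoch, val_loss)
        self.params_ = best[2]
        self.selected_epoch_ = best[1] if best[1] > 0 else 1
        if best[1] == 0:  # no epoch improved over +inf is impossible; ties at epoch 1
            self.selected_epoch_ = 1
        return self

    def predict_bag(self, bag: Bag | list[Patch]):
        """Per-bag class probabilities and attention weights."""
        check_is_fitted(self, "params_")
        patches = bag.patches if isinstance(bag, Bag) else bag
        if not patches:
            raise ValueError("empty bag")
        if patches[0].pixels.shape[0] != self._cfg.patch_size:
            raise ValueError("patch size does not match model configuration")
        F = _pool_features(patches, self._cfg.pool_grid)
        probs, a, _ = self._forward(F)
        return probs, a

    def predict_slide_proba(self, bags: list[Bag]) -> np.ndarray:
        probs = [self.predict_bag(b)[0] for b in bags]
        return aggregate_slide(probs)

    def predict(self, slides: dict, seed: int = 0) -> np.ndarray:
        """Predict a label per slide from freshly sampled bags."""
        check_is_fitted(self, "params_")
        cfg = self._cfg
        out = []
        for sid in slides:
            d = slides[sid]
            mask = d.get("mask")
            if mask is None:
                mask = detect_tissue(d["image"])
            patches = extract_patches(
                d["image"], np.asarray(mask, dtype=bool), cfg.patch_size,
                cfg.max_patches, cfg.min_tissue_fraction, seed=seed, slide_id=sid,
            )
            bag_size = min(cfg.bag_size, len(patches))
            bags = make_bags(patches, cfg.n_bags, bag_size, seed=seed + 1)
            out.append(int(np.argmax(self.predict_slide_proba(bags))))
        return np.asarray(out)


def attention_heatmap(
    model: AttentionMILClassifier, slide_shape: tuple[int, int], bags: list[Bag]
) -> np.ndarray:
    """Attention map over the slide: per-bag min-max normalized weights painted
    onto patch footprints, overlaps averaged.

    Returns a float array in [0, 1] (NaN-free; regions never covered are 0).
    A constant attention vector within a bag normalizes to all-zeros.
    """
    acc = np.zeros(slide_shape, dtype=float)
    cnt = np.zeros(slide_shape, dtype=float)
    for bag in bags:
        _, a = model.predict_bag(bag)
        lo, hi = a.min(), a.max()
        norm = np.zeros_like(a) if hi - lo < 1e-15 else (a - lo) / (hi - lo)
        P = bag.patches[0].pixels.shape[0]
        for w, patch in zip(norm, bag.patches):
            r, c = patch.location
            acc[r : r + P, c : c + P] += w
            cnt[r : r + P, c : c + P] += 1
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return out


def save_heatmap_png(heat: np.ndarray, path, thumbnail: np.ndarray | None = None) -> None:
    """Render a blue-to-red heatmap PNG, optionally over a slide thumbnail."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if thumbnail is not None:
        ax.imshow(thumbnail)
        ax.imshow(heat, cmap="coolwarm", alpha=0.5, vmin=0, vmax=1)
    else:
        ax.imshow(heat, cmap="coolwarm", vmin=0, vmax=1)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
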