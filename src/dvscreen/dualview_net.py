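"""Breast-wise dual-view abnormality classifier with cross-view feature alignment.

The model judges one breast from its two projections. Each view passes through
its own feature extractor producing a d-dimensional vector; a learnable linear
transformation block maps the MLO vector toward the CC feature space,

    v*_mlo = wᵀ v_mlo                                         (no bias term)

and a sigmoid head classifies the concatenation [v_cc ; v*_mlo]. Training
minimizes the combined objective

    L = α · CE + β · cos_loss,      0 ≤ α, β ≤ 1

where CE is the mean binary cross-entropy of the head and cos_loss the mean
cosine distance 1 − cos(v_cc, v*_mlo). The alignment term is auxiliary: it
pulls the transformed MLO representation toward the CC representation of the
same breast, so α defaults to 1.0 and β to a small 0.1 — classification must
dominate the gradient while alignment regularizes the transform.

Feature extraction is a pluggable contract (any ``image -> vector`` callable
with fixed output length). Production systems plug in a pretrained CNN; this
package ships :class:`TinyBackbone`, a compact extractor — fixed average
pooling to a g×g grid followed by a learnable dense+ReLU layer — that trains
in seconds on a CPU and exposes exactly the same interface, losses and
optimizer path.

Optimization is plain Adam (default learning rate 3e-4) with early stopping on
the validation combined loss, implemented here directly in NumPy together with
the exact gradients of both loss terms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .imaging import BreastExam, resize_for_model, standardize_orientation

logger = logging.getLogger("dvscreen.dualview_net")

#: Probability clamp inside the cross-entropy, for numerical safety.
EPS = 1e-7

CHECKPOINT_VERSION = "dvscreen-checkpoint-1"


# ---------------------------------------------------------------------------
# Losses and the linear transformation block
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossConfig:
    """Weights of the combined objective; both constrained to [0, 1]."""

    alpha: float = 1.0
    beta: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError(f"alpha and beta must lie in [0,1], got {self.alpha}, {self.beta}")


@dataclass
class TransformBlock:
    """The learnable d×d linear map applied to MLO features (no bias)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError(f"w must be a square matrix, got shape {self.w.shape}")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("w must contain finite entries")

    @property
    def d(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class FeatureBundle:
    """Per-breast feature vectors: raw CC, raw MLO, and the transformed MLO."""

    v_cc: np.ndarray
    v_mlo: np.ndarray
    v_star_mlo: np.ndarray
    d: int


def transform_mlo(v_mlo: np.ndarray, block: TransformBlock | np.ndarray) -> np.ndarray:
    """Apply the linear transformation block: returns wᵀ · v_mlo."""
    w = block.w if isinstance(block, TransformBlock) else np.asarray(block, dtype=float)
    v = np.asarray(v_mlo, dtype=float)
    if v.ndim != 1 or w.shape != (v.size, v.size):
        raise ValueError(f"shape mismatch: w {w.shape} vs v_mlo {v.shape}")
    return w.T @ v


def cross_entropy_loss(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Mean binary cross-entropy −(1/N) Σ [y log ŷ + (1−y) log(1−ŷ)].

    Predictions are clamped to [EPS, 1−EPS] before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    if y.shape != p.shape or y.ndim != 1 or y.size == 0:
        raise ValueError(f"label/prediction shape mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cosine_alignment_loss(v_cc: np.ndarray, v_star_mlo: np.ndarray) -> float:
    """Cosine distance 1 − cos(v_cc, v*_mlo), in [0, 2].

    The formula is undefined for a zero vector; that degenerate case returns 0
    with a logged warning rather than penalizing an arbitrary direction.
    """
    a = np.asarray(v_cc, dtype=float)
    b = np.asarray(v_star_mlo, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vector shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("cosine_alignment_loss: zero-norm feature vector; returning 0")
        return 0.0
    return float(1.0 - (a @ b) / (na * nb))


def combined_loss(ce: float, cos_loss: float, cfg: LossConfig) -> float:
    """The training objective α·CE + β·cos_loss."""
    return cfg.alpha * ce + cfg.beta * cos_loss


# ---------------------------------------------------------------------------
# Backbone contract and the compact reference backbone
# ---------------------------------------------------------------------------

@runtime_checkable
class BackboneContract(Protocol):
    """A feature extractor: deterministic (in eval) map image → length-d vector."""

    descriptor: str
    d: int

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


def _pool_grid(image: np.ndarray, grid: int) -> np.ndarray:
    """Fixed average pooling of a 2-D image onto a grid×grid grid, flattened."""
    img = np.asarray(image, dtype=float)
    rows = np.array_split(np.arange(img.shape[0]), grid)
    cols = np.array_split(np.arange(img.shape[1]), grid)
    out = np.empty((grid, grid), dtype=float)
    for i, rsel in enumerate(rows):
        band = img[rsel]
        for j, csel in enumerate(cols):
            out[i, j] = band[:, csel].mean()
    return out.ravel()


@dataclass
class TinyBackbone:
    """Compact trainable extractor: fixed g×g average pooling + dense ReLU layer.

    ``W1`` has shape (d, g²); features are relu(W1 · pooled + b1). Weights are
    seeded at construction so identical seeds give identical extractors.
    """

    W1: np.ndarray
    b1: np.ndarray
    grid: int
    descriptor: str = "tiny:avgpool+dense-relu"

    @classmethod
    def create(cls, d: int = 32, grid: int = 8, seed: int = 0) -> "TinyBackbone":
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(grid * grid)
        return cls(W1=rng.normal(0.0, scale, size=(d, grid * grid)),
                   b1=np.zeros(d), grid=grid)

    @property
    def d(self) -> int:
        return self.W1.shape[0]

    def pooled(self, image: np.ndarray) -> np.ndarray:
        return _pool_grid(image, self.grid)

    def features_from_pooled(self, p: np.ndarray) -> np.ndarray:
        return np.maximum(p @ self.W1.T + self.b1, 0.0)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.features_from_pooled(self.pooled(image))


# ---------------------------------------------------------------------------
# The dual-view model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; YAML-serializable via :func:`load_config`."""

    d: int = 32
    grid: int = 8
    alpha: float = 1.0
    beta: float = 0.1
    learning_rate: float = 3e-4
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 32
    seed: int = 0
    image_side: int = 128
    share_backbones: bool = False
    backbone: str = "tiny"

    @property
    def loss(self) -> LossConfig:
        return LossConfig(alpha=self.alpha, beta=self.beta)


def load_config(path: str | Path) -> TrainConfig:
    """Read a TrainConfig from a YAML key-value file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    return TrainConfig(**data)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DualViewModel:
    """Two backbones + linear transformation block + sigmoid head."""

    def __init__(self, backbone_cc: TinyBackbone, backbone_mlo: TinyBackbone,
                 block: TransformBlock, head_w: np.ndarray, head_b: float,
                 cfg: TrainConfig):
        if backbone_cc.d != backbone_mlo.d or backbone_cc.d != block.d:
            raise ValueError("backbones and transform block disagree on feature dimension d")
        if head_w.shape != (2 * block.d,):
            raise ValueError(f"head expects weight length {2 * block.d}, got {head_w.shape}")
        self.backbone_cc = backbone_cc
        self.backbone_mlo = backbone_mlo
        self.block = block
        self.head_w = np.asarray(head_w, dtype=float)
        self.head_b = float(head_b)
        self.cfg = cfg
        # Per-view standardization of pooled inputs, fitted on the training
        # set by train(); identity until then.
        self.pool_mu_cc: np.ndarray | None = None
        self.pool_sd_cc: np.ndarray | None = None
        self.pool_mu_mlo: np.ndarray | None = None
        self.pool_sd_mlo: np.ndarray | None = None

    def set_pool_stats(self, Pc: np.ndarray, Pm: np.ndarray) -> None:
        """Fit input standardization (mean/sd per pooled cell) on training data."""
        self.pool_mu_cc = Pc.mean(axis=0)
        self.pool_sd_cc = np.maximum(Pc.std(axis=0), 1e-6)
        self.pool_mu_mlo = Pm.mean(axis=0)
        self.pool_sd_mlo = np.maximum(Pm.std(axis=0), 1e-6)

    def normalize_pooled(self, p_cc: np.ndarray, p_mlo: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
        if self.pool_mu_cc is None:
            return p_cc, p_mlo
        return ((p_cc - self.pool_mu_cc) / self.pool_sd_cc,
                (p_mlo - self.pool_mu_mlo) / self.pool_sd_mlo)

    @classmethod
    def create(cls, cfg: TrainConfig) -> "DualViewModel":
        bb_cc = TinyBackbone.create(cfg.d, cfg.grid, seed=cfg.seed)
        bb_mlo = bb_cc if cfg.share_backbones else TinyBackbone.create(cfg.d, cfg.grid, seed=cfg.seed + 1)
        rng = np.random.default_rng(cfg.seed + 2)
        block = TransformBlock(w=np.eye(cfg.d) + rng.normal(0, 0.01, size=(cfg.d, cfg.d)))
        head_w = rng.normal(0, 0.01, size=2 * cfg.d)
        return cls(bb_cc, bb_mlo, block, head_w, 0.0, cfg)

    @property
    def d(self) -> int:
        return self.block.d

    # -- inference ----------------------------------------------------------

    def preprocess(self, exam: BreastExam) -> tuple[np.ndarray, np.ndarray]:
        """Standardize orientation, resize, and average-pool both views."""
        side = self.cfg.image_side
        cc = resize_for_model(standardize_orientation(exam.cc), side)
        mlo = resize_for_model(standardize_orientation(exam.mlo), side)
        return self.backbone_cc.pooled(cc), self.backbone_mlo.pooled(mlo)

    def forward(self, exam_or_pooled) -> tuple[float, FeatureBundle]:
        """Probability of abnormality and the feature bundle for one breast."""
        if isinstance(exam_or_pooled, BreastExam):
            p_cc, p_mlo = self.preprocess(exam_or_pooled)
        else:
            p_cc, p_mlo = exam_or_pooled
        p_cc, p_mlo = self.normalize_pooled(p_cc, p_mlo)
        v_cc = self.backbone_cc.features_from_pooled(p_cc)
        v_mlo = self.backbone_mlo.features_from_pooled(p_mlo)
        v_star = transform_mlo(v_mlo, self.block)
        z = np.concatenate([v_cc, v_star]) @ self.head_w + self.head_b
        prob = float(_sigmoid(np.array([z]))[0])
        return prob, FeatureBundle(v_cc=v_cc, v_mlo=v_mlo, v_star_mlo=v_star, d=self.d)

    def predict_proba(self, exams: Sequence[BreastExam]) -> np.ndarray:
        return np.array([self.forward(e)[0] for e in exams])

    def _forward_batch(self, Pc: np.ndarray, Pm: np.ndarray) -> dict:
        d = self.d
        Hc = Pc @ self.backbone_cc.W1.T + self.backbone_cc.b1
        Hm = Pm @ self.backbone_mlo.W1.T + self.backbone_mlo.b1
        Vc, Vm = np.maximum(Hc, 0.0), np.maximum(Hm, 0.0)
        Vs = Vm @ self.block.w          # row form of v* = wᵀ v
        z = Vc @ self.head_w[:d] + Vs @ self.head_w[d:] + self.head_b
        p = _sigmoid(z)
        return {"Hc": Hc, "Hm": Hm, "Vc": Vc, "Vm": Vm, "Vs": Vs, "z": z, "p": p}

    def mean_cosine_distance(self, exams: Sequence[BreastExam]) -> float:
        """Mean 1 − cos(v_cc, v*_mlo) over a set of exams (alignment diagnostic)."""
        vals = []
        for e in exams:
            _, fb = self.forward(e)
            vals.append(cosine_alignment_loss(fb.v_cc, fb.v_star_mlo))
        return float(np.mean(vals))

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {"version": CHECKPOINT_VERSION, "cfg": asdict(self.cfg)}
        n_pool = self.backbone_cc.W1.shape[1]
        arrays = dict(meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                      W1c=self.backbone_cc.W1, b1c=self.backbone_cc.b1,
                      W1m=self.backbone_mlo.W1, b1m=self.backbone_mlo.b1,
                      w=self.block.w, head_w=self.head_w, head_b=np.array([self.head_b]),
                      mu_cc=self.pool_mu_cc if self.pool_mu_cc is not None else np.zeros(n_pool),
                      sd_cc=self.pool_sd_cc if self.pool_sd_cc is not None else np.ones(n_pool),
                      mu_mlo=self.pool_mu_mlo if self.pool_mu_mlo is not None else np.zeros(n_pool),
                      sd_mlo=self.pool_sd_mlo if self.pool_sd_mlo is not None else np.ones(n_pool))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DualViewModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            cfg = TrainConfig(**meta["cfg"])
            bb_cc = TinyBackbone(W1=z["W1c"].copy(), b1=z["b1c"].copy(), grid=cfg.grid)
            bb_mlo = bb_cc if cfg.share_backbones else TinyBackbone(
                W1=z["W1m"].copy(), b1=z["b1m"].copy(), grid=cfg.grid)
            model = cls(bb_cc, bb_mlo, TransformBlock(w=z["w"].copy()),
                        z["head_w"].copy(), float(z["head_b"][0]), cfg)
            model.pool_mu_cc = z["mu_cc"].copy()
            model.pool_sd_cc = z["sd_cc"].copy()
            model.pool_mu_mlo = z["mu_mlo"].copy()
            model.pool_sd_mlo = z["sd_mlo"].copy()
            return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def prepare_dataset(exams: Sequence[BreastExam], model: DualViewModel
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Pool all views once; returns (Pcc, Pmlo, y, study_ids)."""
    Pc, Pm, y, sids = [], [], [], []
    for e in exams:
        if e.label is None:
            raise ValueError(f"exam {e.study_id}/{e.laterality} has no label")
        pc, pm = model.preprocess(e)
        Pc.append(pc)
        Pm.append(pm)
        y.append(e.label)
        sids.append(e.study_id)
    return np.array(Pc), np.array(Pm), np.array(y, dtype=float), sids


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_losses(model: DualViewModel, Pc, Pm, y, cfg: LossConfig) -> tuple[float, float, float]:
    f = model._forward_batch(Pc, Pm)
    ce = cross_entropy_loss(y, f["p"])
    na = np.linalg.norm(f["Vc"], axis=1)
    nb = np.linalg.norm(f["Vs"], axis=1)
    ok = (na > 0) & (nb > 0)
    cos = np.zeros(len(y))
    cos[ok] = 1.0 - np.einsum("ij,ij->i", f["Vc"][ok], f["Vs"][ok]) / (na[ok] * nb[ok])
    cos_loss = float(cos.mean())
    return ce, cos_loss, combined_loss(ce, cos_loss, cfg)


def _grads(model: DualViewModel, Pc, Pm, y, cfg: LossConfig) -> dict[str, np.ndarray]:
    """Exact gradients of α·CE + β·mean(1 − cos) for one minibatch."""
    d, N = model.d, len(y)
    f = model._forward_batch(Pc, Pm)
    Vc, Vm, Vs = f["Vc"], f["Vm"], f["Vs"]

    dz = cfg.alpha * (f["p"] - y) / N                       # dCE/dz
    g_head_w = np.concatenate([Vc.T @ dz, Vs.T @ dz])
    g_head_b = float(dz.sum())
    dVc = np.outer(dz, model.head_w[:d])
    dVs = np.outer(dz, model.head_w[d:])

    if cfg.beta > 0:
        na = np.linalg.norm(Vc, axis=1)
        nb = np.linalg.norm(Vs, axis=1)
        ok = (na > 0) & (nb > 0)
        if ok.any():
            a, b = Vc[ok], Vs[ok]
            naok, nbok = na[ok, None], nb[ok, None]
            cosv = np.einsum("ij,ij->i", a, b)[:, None] / (naok * nbok)
            # d(1−cos)/da = cos·a/|a|² − b/(|a||b|)
            dVc[ok] += cfg.beta / N * (cosv * a / naok ** 2 - b / (naok * nbok))
            dVs[ok] += cfg.beta / N * (cosv * b / nbok ** 2 - a / (naok * nbok))

    g_w = Vm.T @ dVs                                        # v* = Vm w
    dVm = dVs @ model.block.w.T
    dHc = dVc * (f["Hc"] > 0)
    dHm = dVm * (f["Hm"] > 0)
    grads = {"W1c": dHc.T @ Pc, "b1c": dHc.sum(axis=0),
             "W1m": dHm.T @ Pm, "b1m": dHm.sum(axis=0),
             "w": g_w, "head_w": g_head_w, "head_b": np.array(g_head_b)}
    if model.backbone_mlo is model.backbone_cc:
        grads["W1c"] = grads["W1c"] + grads.pop("W1m")
        grads["b1c"] = grads["b1c"] + grads.pop("b1m")
    return grads


def train(train_exams: Sequence[BreastExam], val_exams: Sequence[BreastExam],
          cfg: TrainConfig | None = None) -> tuple[DualViewModel, list[dict]]:
    """Train the dual-view classifier with Adam and early stopping.

    Raises on study leakage (any study_id present in both sets). Monitors the
    validation combined loss; training halts after ``patience`` epochs without
    improvement and the best-epoch parameters are restored. Returns the model
    and a per-epoch history (losses on both splits, validation AUC when both
    classes are present).
    """
    cfg = cfg or TrainConfig()
    if not train_exams or not val_exams:
        raise ValueError("train and validation sets must be nonempty")
    train_sids = {e.study_id for e in train_exams}
    val_sids = {e.study_id for e in val_exams}
    leaked = train_sids & val_sids
    if leaked:
        raise ValueError(f"study leakage between train and validation sets: {sorted(leaked)[:5]}")

    model = DualViewModel.create(cfg)
    Pc, Pm, y, _ = prepare_dataset(train_exams, model)
    Pcv, Pmv, yv, _ = prepare_dataset(val_exams, model)
    model.set_pool_stats(Pc, Pm)
    Pc, Pm = model.normalize_pooled(Pc, Pm)
    Pcv, Pmv = model.normalize_pooled(Pcv, Pmv)

    params = {"W1c": model.backbone_cc.W1, "b1c": model.backbone_cc.b1,
              "w": model.block.w, "head_w": model.head_w,
              "head_b": np.array(model.head_b)}
    if model.backbone_mlo is not model.backbone_cc:
        params["W1m"] = model.backbone_mlo.W1
        params["b1m"] = model.backbone_mlo.b1
    opt = _Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1000)
    loss_cfg = cfg.loss

    history: list[dict] = []
    best_val = np.inf
    best_state: dict[str, np.ndarray] = {}
    best_epoch = -1
    n = len(y)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            grads = _grads(model, Pc[sel], Pm[sel], y[sel], loss_cfg)
            opt.step(params, grads)
            model.head_b = float(params["head_b"])
        tr_ce, tr_cos, tr_loss = _batch_losses(model, Pc, Pm, y, loss_cfg)
        va_ce, va_cos, va_loss = _batch_losses(model, Pcv, Pmv, yv, loss_cfg)
        rec = {"epoch": epoch, "train_ce": tr_ce, "train_cos": tr_cos, "train_loss": tr_loss,
               "val_ce": va_ce, "val_cos": va_cos, "val_loss": va_loss}
        if 0 < yv.sum() < len(yv):
            from sklearn.metrics import roc_auc_score

            pv = model._forward_batch(Pcv, Pmv)["p"]
            rec["val_auc"] = float(roc_auc_score(yv, pv))
        history.append(rec)
        if va_loss < best_val - 1e-6:
            best_val = va_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in params.items()}
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    for k, v in best_state.items():
        params[k][...] = v
    model.head_b = float(params["head_b"])
    return model, history
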