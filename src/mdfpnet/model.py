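"""The four-branch parallel classifier and its trainable fusion head.

Each acoustic feature (mel spectrogram, MFCC, LFCC, time-averaged MFCC) is
classified by its own CNN branch ending in a softmax over the species
classes.  The four 6-long probability vectors are concatenated into a
24-long vector and mapped to the final class probabilities by a trainable
fully connected layer — a late-fusion design whose learnable weights
generalise simple prediction averaging (averaging is an exact special case
of the head, used as its initialisation).

Branches are trained independently with SGD + momentum on cross-entropy,
then frozen while the fusion head is trained on their outputs.  Deep
pretrained backbones (densenet201, mobilenet, xception) are pluggable via
:func:`register_backbone`; the built-in ``cnn1d`` (the bespoke 1-D branch)
and ``tiny2d`` (a small 4-block 2-D CNN) train at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import nn
from .features import FeatureSet, to_branch_input

__all__ = [
    "BRANCH_ORDER",
    "BranchSpec",
    "Branch",
    "TrainConfig",
    "FusionHead",
    "softmax",
    "cross_entropy",
    "build_cnn1d",
    "build_tiny2d",
    "build_branch",
    "register_backbone",
    "prepare_branch_input",
    "train_branch",
    "fuse_and_predict",
    "train_fusion",
]

#: fixed concatenation order of the branches in the fusion vector
BRANCH_ORDER = ("mel", "mfcc", "lfcc", "mean_mfcc")

_FEATURES_2D = ("mel", "mfcc", "lfcc")
_BACKBONES_2D = ("tiny2d", "densenet201", "mobilenet", "xception")


# ---------------------------------------------------------------------------
# elementary ops


def softmax(x) -> np.ndarray:
    """Normalised exponentials of a logit vector (or batch of rows).

    Computed max-shifted for numerical stability; invariant under adding a
    constant to all logits.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax input must be finite")
    return nn.softmax_logits(x)


def cross_entropy(P, Y) -> float:
    """Mean negative log-probability of the true class.

    ``P`` is a batch of predicted probability rows, ``Y`` a batch of one-hot
    label rows; probabilities are clipped to [1e-12, 1].
    """
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: predictions {P.shape} vs labels {Y.shape}")
    if not (np.all((Y == 0) | (Y == 1)) and np.all(Y.sum(axis=1) == 1)):
        raise ValueError("label rows must be one-hot")
    p_true = np.clip((P * Y).sum(axis=1), 1e-12, 1.0)
    return float(-np.log(p_true).mean())


# ---------------------------------------------------------------------------
# branch construction


@dataclass(frozen=True)
class BranchSpec:
    feature: str  # mel | mfcc | lfcc | mean_mfcc
    backbone: str  # cnn1d | tiny2d | densenet201 | mobilenet | xception
    input_shape: tuple[int, ...]  # (C, H, W) for 2-D, (length,) for 1-D
    n_classes: int = 6

    def __post_init__(self) -> None:
        if self.feature not in BRANCH_ORDER:
            raise ValueError(f"unknown feature {self.feature!r}")
        # pairing is enforced for the built-in identifiers; unrecognised
        # names are left to build_branch, which knows the plug-in registry
        if self.feature == "mean_mfcc":
            if self.backbone != "cnn1d":
                raise ValueError("mean_mfcc pairs only with the 1-D backbone 'cnn1d'")
        elif self.backbone == "cnn1d":
            raise ValueError(f"2-D feature {self.feature!r} cannot use the 1-D backbone 'cnn1d'")


@dataclass
class Branch:
    spec: BranchSpec
    net: nn.Sequential


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 15
    seed: int = 0
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def build_cnn1d(
    input_len: int = 128,
    n_classes: int = 6,
    seed: int = 0,
    dropout: float = 0.25,
) -> nn.Sequential:
    """The bespoke 1-D CNN branch.

    Four blocks of (16 kernels of size 3, stride 1, ReLU, dropout, max-pool
    of size 2 and stride 2); a 128-long input flattens to 8 frames x 16
    channels = 128, followed by dense 128 -> dense n_classes -> softmax.
    """
    if input_len % 16 != 0:
        raise ValueError(f"input_len must be divisible by 2^4, got {input_len}")
    rng = np.random.default_rng(seed)
    streams = rng.spawn(16)
    layers: list[nn.Layer] = []
    c_in = 1
    for i in range(4):
        layers += [
            nn.Conv1D(c_in, 16, 3, streams[i]),
            nn.ReLU(),
            nn.Dropout(dropout, streams[4 + i]),
            nn.MaxPool1D(2),
        ]
        c_in = 16
    flat = 16 * (input_len // 16)
    layers += [
        nn.Flatten(),
        nn.Dropout(dropout, streams[8]),
        nn.Dense(flat, 128, streams[9]),
        nn.ReLU(),
        nn.Dense(128, n_classes, streams[10], init="glorot"),
    ]
    net = nn.Sequential(layers)
    net.n_classes = n_classes
    return net


def build_tiny2d(
    input_shape: tuple[int, int, int],
    n_classes: int = 6,
    seed: int = 0,
    dropout: float = 0.25,
    channels: tuple[int, int, int, int] = (8, 8, 16, 16),
) -> nn.Sequential:
    """A small fixed 4-conv-block 2-D CNN for desk-scale training.

    Conv(3x3, same) -> ReLU -> max-pool(2) four times, then a 64-unit dense
    layer and the class head.  Input is (C, H, W) with identical channels.
    """
    c, h, w = input_shape
    rng = np.random.default_rng(seed)
    streams = rng.spawn(8)
    layers: list[nn.Layer] = []
    c_in = c
    for i, c_out in enumerate(channels):
        layers += [nn.Conv2D(c_in, c_out, 3, streams[i]), nn.ReLU(), nn.MaxPool2D(2)]
        c_in = c_out
        h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError(f"input {input_shape} too small for 4 pooling stages")
    flat = c_in * h * w
    layers += [
        nn.Flatten(),
        nn.Dropout(dropout, streams[4]),
        nn.Dense(flat, 64, streams[5]),
        nn.ReLU(),
        nn.Dense(64, n_classes, streams[6], init="glorot"),
    ]
    net = nn.Sequential(layers)
    net.n_classes = n_classes
    return net


BackboneFactory = Callable[[BranchSpec, int, float], nn.Sequential]
_BACKBONE_REGISTRY: dict[str, BackboneFactory] = {}


def register_backbone(name: str, factory: BackboneFactory) -> None:
    """Register a backbone factory ``(spec, seed, dropout) -> Sequential``.

    The deep pretrained backbones are served through this hook; the package
    itself ships only the desk-scale ``cnn1d`` and ``tiny2d``.
    """
    _BACKBONE_REGISTRY[name] = factory


def build_branch(
    spec: BranchSpec,
    pretrained=None,
    seed: int = 0,
    dropout: float = 0.25,
) -> Branch:
    """Build a branch network for ``spec``.

    ``pretrained`` is an optional state dict loaded into the network after
    construction.  Random initialisation is fully determined by ``seed``.
    """
    known = ("cnn1d", "tiny2d") + tuple(_BACKBONE_REGISTRY)
    if spec.backbone == "cnn1d":
        net = build_cnn1d(spec.input_shape[-1], spec.n_classes, seed=seed, dropout=dropout)
    elif spec.backbone == "tiny2d":
        net = build_tiny2d(tuple(spec.input_shape), spec.n_classes, seed=seed, dropout=dropout)
    elif spec.backbone in _BACKBONE_REGISTRY:
        net = _BACKBONE_REGISTRY[spec.backbone](spec, seed, dropout)
    elif spec.backbone in _BACKBONES_2D:
        raise ValueError(
            f"backbone {spec.backbone!r} needs an external deep-learning runtime; "
            f"register a factory with register_backbone() or use 'tiny2d'"
        )
    else:
        raise ValueError(f"unknown backbone {spec.backbone!r}; known: {known}")
    if pretrained is not None:
        net.load_state_dict(pretrained)
    return Branch(spec=spec, net=net)


# ---------------------------------------------------------------------------
# per-branch input preparation


def prepare_branch_input(F: FeatureSet, spec: BranchSpec) -> np.ndarray:
    """Turn one clip's :class:`FeatureSet` into the array ``spec`` expects."""
    if spec.feature == "mean_mfcc":
        v = np.asarray(F.mean_mfcc, dtype=np.float64)
        lo, hi = v.min(), v.max()
        v = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        return v[None, :].astype(np.float32)  # (1, length)
    matrix = {"mel": F.mel.values, "mfcc": F.mfcc.values, "lfcc": F.lfcc.values}[spec.feature]
    channels, h, w = spec.input_shape
    native = (matrix.shape[1], matrix.shape[0])  # frequency x time
    target = None if (h, w) == native else (h, w)
    return to_branch_input(matrix, target_shape=target, channels=channels).astype(np.float32)


# ---------------------------------------------------------------------------
# training


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_branch(branch: Branch, dataset: tuple[np.ndarray, np.ndarray], cfg: TrainConfig) -> list[float]:
    """Train one branch with SGD on cross-entropy; returns per-epoch losses.

    ``dataset`` is ``(X, y)`` with X matching the branch input shape and y
    integer class labels.  Deterministic given ``cfg.seed``.
    """
    X, y = dataset
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("dataset must be non-empty")
    n_classes = branch.net.n_classes
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes}), got range [{y.min()}, {y.max()}]")
    opt = nn.SGD(branch.net, lr=cfg.lr, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    history = []
    for _ in range(cfg.epochs):
        losses, weights = [], []
        for idx in _iterate_batches(len(y), cfg.batch_size, rng):
            logits = branch.net.forward(X[idx], train=True)
            loss, _, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            branch.net.backward(dlogits.astype(np.float32))
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    return history


# ---------------------------------------------------------------------------
# fusion


@dataclass
class FusionHead:
    """Fully connected map from the concatenated branch outputs to classes.

    With ``activation='identity'`` the head output is the affine map itself
    (used for the exact averaging special case, which already lies on the
    probability simplex); trained heads use ``'softmax'``.
    """

    W: np.ndarray  # (n_branches * n_classes, n_classes)
    b: np.ndarray  # (n_classes,)
    activation: str = "softmax"
    n_branches: int = 4

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.activation not in ("softmax", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.W.shape[0] != self.n_branches * self.W.shape[1]:
            raise ValueError(f"fusion weight shape {self.W.shape} inconsistent with {self.n_branches} branches")

    @property
    def n_classes(self) -> int:
        return self.W.shape[1]

    @classmethod
    def averaging(cls, n_branches: int = 4, n_classes: int = 6) -> "FusionHead":
        """The head whose output is the plain mean of the branch predictions."""
        W = np.tile(np.eye(n_classes) / n_branches, (n_branches, 1))
        return cls(W=W, b=np.zeros(n_classes), activation="identity", n_branches=n_branches)

    def predict(self, concat: np.ndarray) -> np.ndarray:
        """Map (batch of) 24-long concatenated branch outputs to class probabilities."""
        z = np.atleast_2d(np.asarray(concat, dtype=np.float64)) @ self.W + self.b
        out = z if self.activation == "identity" else nn.softmax_logits(z)
        return out[0] if np.ndim(concat) == 1 else out


def _check_branches(branches: Sequence[Branch]) -> list[Branch]:
    if len(branches) != len(BRANCH_ORDER):
        raise ValueError(f"expected {len(BRANCH_ORDER)} branches, got {len(branches)}")
    by_feature = {b.spec.feature: b for b in branches}
    if set(by_feature) != set(BRANCH_ORDER):
        raise ValueError(f"branches must cover {BRANCH_ORDER}, got {sorted(by_feature)}")
    return [by_feature[f] for f in BRANCH_ORDER]


def concat_branch_outputs(branches: Sequence[Branch], F: FeatureSet) -> np.ndarray:
    """The 24-long fusion input: branch probabilities in fixed order."""
    ordered = _check_branches(branches)
    parts = []
    for branch in ordered:
        x = prepare_branch_input(F, branch.spec)[None, ...]
        parts.append(branch.net.predict_proba(x)[0])
    return np.concatenate(parts)


def fuse_and_predict(branches: Sequence[Branch], head: FusionHead, F: FeatureSet) -> np.ndarray:
    """Final class probabilities for one clip from the fused branches."""
    return head.predict(concat_branch_outputs(branches, F))


def train_fusion(
    head: FusionHead,
    dataset: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[FusionHead, list[float]]:
    """Train the fusion layer on frozen-branch outputs.

    ``dataset`` is ``(Z, y)`` where Z rows are the 24-long concatenated
    branch probability vectors.  Returns a softmax-activated head and the
    per-epoch loss history.  The input head provides the initial weights
    (the averaging head is a natural starting point).
    """
    Z, y = dataset
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if Z.ndim != 2 or Z.shape[1] != head.W.shape[0]:
        raise ValueError(f"fusion inputs of width {Z.shape[-1]} do not match head ({head.W.shape[0]})")
    W = head.W.copy()
    b = head.b.copy()
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    rng = np.random.default_rng(cfg.seed)
    history = []
    for _ in range(cfg.epochs):
        losses, weights = [], []
        for idx in _iterate_batches(len(y), cfg.batch_size, rng):
            logits = Z[idx] @ W + b
            loss, _, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            gW = Z[idx].T @ dlogits
            gb = dlogits.sum(axis=0)
            vW = cfg.momentum * vW - cfg.lr * gW
            vb = cfg.momentum * vb - cfg.lr * gb
            W += vW
            b += vb
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    return FusionHead(W=W, b=b, activation="softmax", n_branches=head.n_branches), history
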