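"""Training: label-smoothing loss, stratified splitting, class-balanced
sampling, the Adam schedule with per-group learning rates, and the fit loop
with validation-based model selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, log_softmax
from .network import MMMINet, ModelConfig, N_CLASSES

log = logging.getLogger(__name__)

__all__ = ["LossConfig", "SplitAssignment", "OptimSchedule",
           "label_smoothing_loss", "stratified_split", "make_weighted_sampler",
           "Adam", "train"]


@dataclass
class LossConfig:
    """Label-smoothing cross entropy: the one-hot target is mixed with the
    uniform prior u(y|x) = 1/K, weighted by epsilon."""

    epsilon: float = 0.1
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def label_smoothing_loss(probs, labels, config: LossConfig = LossConfig()) -> float:
    """Mean over samples of (1-eps) * (-log q_true) + eps/K * sum_y(-log q_y).

    Reduces to cross entropy at eps = 0 and equals ln K for uniform
    predictions at any eps.  Probabilities are clamped at 1e-12 before the
    log (clamping is logged).
    """
    q = np.asarray(probs, float)
    y = np.asarray(labels, int)
    if q.ndim == 1:
        q = q[None, :]
        y = np.atleast_1d(y)
    K = config.n_classes
    if q.shape[1] != K:
        raise ValueError("probability rows do not match n_classes")
    if np.any(np.abs(q.sum(axis=1) - 1) > 1e-6) or q.min() < -1e-12:
        raise ValueError("probability rows must lie on the simplex")
    if (y < 0).any() or (y >= K).any():
        raise ValueError("labels out of range")
    if (q < 1e-12).any():
        log.warning("clamping %d zero probabilities", int((q < 1e-12).sum()))
        q = np.clip(q, 1e-12, None)
    logq = np.log(q)
    ce = -logq[np.arange(len(y)), y]
    smooth = -logq.sum(axis=1) / K
    return float(np.mean((1 - config.epsilon) * ce + config.epsilon * smooth))


def _smoothing_loss_t(logits: Tensor, label: int, config: LossConfig) -> Tensor:
    """Differentiable single-sample loss on logits."""
    lq = log_softmax(logits, axis=-1)
    eps, K = config.epsilon, config.n_classes
    ce = -lq[0, int(label)]
    smooth = -lq.sum() * (1.0 / K)
    return ce * (1 - eps) + smooth * eps


# ---------------------------------------------------------------------------
# splitting and sampling
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    partition: dict                      # patient_id -> train|val|test
    fractions: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def indices(self, ids) -> dict:
        ids = [str(i) for i in ids]
        return {p: np.array([k for k, i in enumerate(ids)
                             if self.partition[i] == p], int)
                for p in ("train", "val", "test")}


def stratified_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 0,
                     ids=None) -> SplitAssignment:
    """Label-stratified random partition with largest-remainder rounding.

    Within each class the shuffled members are allotted to train/val/test so
    that sizes are floor(f * n_c) plus one extra for the largest fractional
    remainders (ties resolved in partition order train, val, test).  A class
    with fewer members than partitions goes entirely to train, with a warning.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(labels)
    n = len(y)
    ids = [str(i) for i in (ids if ids is not None else range(n))]
    rng = np.random.default_rng(seed)
    parts = ("train", "val", "test")
    assign: dict = {}
    for cls in np.unique(y):
        members = np.where(y == cls)[0]
        rng.shuffle(members)
        if len(members) < len(parts):
            log.warning("class %r has %d members; all to train", cls, len(members))
            for i in members:
                assign[ids[i]] = "train"
            continue
        ideal = np.array(fractions) * len(members)
        sizes = np.floor(ideal).astype(int)
        rem = ideal - sizes
        for k in np.argsort(-rem, kind="stable")[: len(members) - sizes.sum()]:
            sizes[k] += 1
        start = 0
        for p, s in zip(parts, sizes):
            for i in members[start:start + s]:
                assign[ids[i]] = p
            start += s
    return SplitAssignment(assign, fractions, seed)


def make_weighted_sampler(labels) -> np.ndarray:
    """Per-sample sampling weights proportional to 1/class_count, normalized
    to sum 1, so expected draws per class are equal."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty label vector")
    _, inv, counts = np.unique(y, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inv]
    return w / w.sum()


# ---------------------------------------------------------------------------
# optimizer and schedule
# ---------------------------------------------------------------------------

@dataclass
class OptimSchedule:
    """Adam (first-moment decay 0.9) with decoupled weight decay 5e-4 and
    per-group learning rates: tabular encoder 1e-2, classifier 1e-3, the rest
    1e-4.  Batch size 8 is honoured by gradient accumulation over per-sample
    passes (bags have variable instance counts, so no padding).  0.02 is kept
    as a legacy single-rate alias."""

    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 8
    lr_tabular: float = 1e-2
    lr_classifier: float = 1e-3
    lr_rest: float = 1e-4
    legacy_lr: float = 0.02
    max_epochs: int = 30
    patience: int = 6
    selection_metric: str = "macro_ovr_auc"

    def __post_init__(self):
        for r in (self.lr_tabular, self.lr_classifier, self.lr_rest):
            if r <= 0:
                raise ValueError("learning rates must be positive")


class Adam:
    """Adam with decoupled weight decay, one learning rate per parameter group."""

    def __init__(self, params: dict, groups: dict, lrs: dict,
                 beta1: float = 0.9, beta2: float = 0.999,
                 weight_decay: float = 5e-4, eps: float = 1e-8):
        self.params = params
        self.lr_of = {name: lrs[g] for g, names in groups.items() for name in names}
        self.b1, self.b2, self.wd, self.eps = beta1, beta2, weight_decay, eps
        self.m = {k: np.zeros_like(params[k].data) for k in self.lr_of}
        self.v = {k: np.zeros_like(params[k].data) for k in self.lr_of}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        for k, lr in self.lr_of.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p = self.params[k]
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------

def _macro_ovr_auc(probs: np.ndarray, y: np.ndarray) -> float:
    from .evaluation import roc_auc

    aucs = []
    for c in range(probs.shape[1]):
        pos = y == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc(probs[:, c], pos.astype(int)).auc)
    return float(np.mean(aucs)) if aucs else np.nan


def predict_cohort(net: MMMINet, bags, X, idx, mode=None) -> np.ndarray:
    out = np.zeros((len(idx), N_CLASSES))
    use_mode = mode or net.config.modality
    for k, i in enumerate(idx):
        bag = None
        if use_mode != "tabular":
            bag = bags[i].features if hasattr(bags[i], "features") else bags[i]
        row = None if use_mode == "image" else X[i]
        out[k], _ = net.predict_proba(bag, row, mode=mode)
    return out


def train(bags, X, labels, split: SplitAssignment,
          schedule: OptimSchedule | None = None,
          loss_config: LossConfig | None = None,
          config: ModelConfig | None = None,
          seed: int = 0, verbose: bool = False):
    """Fit the network; returns (best net, log DataFrame).

    Each epoch draws ``n_train`` samples with replacement under the
    class-balanced sampler, accumulates gradients over ``batch_size``
    per-sample passes before each optimizer step, evaluates the selection
    metric (macro one-vs-rest AUC) on the validation partition, keeps the
    best parameters, and stops early after ``patience`` epochs without
    improvement.  Divergence (non-finite loss) aborts with a state dump.
    """
    schedule = schedule or OptimSchedule()
    loss_config = loss_config or LossConfig()
    y = np.asarray(labels, int)
    config = config or ModelConfig()
    net = MMMINet(config, seed=seed)
    mode = config.modality
    groups = net.parameter_groups(mode)
    lrs = {"tabular": schedule.lr_tabular, "classifier": schedule.lr_classifier,
           "rest": schedule.lr_rest}
    opt = Adam(net.params, groups, lrs, beta1=schedule.momentum,
               weight_decay=schedule.weight_decay)
    trainable = [n for names in groups.values() for n in names]

    ids = [b.patient_id for b in bags] if bags else [str(i) for i in range(len(y))]
    idx = split.indices(ids)
    tr, va = idx["train"], idx["val"]
    # tensor-ify (and cap) every bag once; reused across epochs
    cache = None
    if mode != "tabular" and bags is not None:
        cache = [net._prepare_bag(b.features, seed=seed) for b in bags]
    sampler_w = make_weighted_sampler(y[tr])
    rng = np.random.default_rng(seed)

    best_metric, best_net, since_best = -np.inf, net.copy(), 0
    rows = []
    for epoch in range(schedule.max_epochs):
        order = rng.choice(tr, size=len(tr), replace=True, p=sampler_w)
        losses, accum, n_in_batch = [], None, 0
        for i in order:
            bag = None if mode == "tabular" else cache[i]
            row = None if mode == "image" else X[i]
            logits, _ = net.forward(bag, row, mode=mode)
            loss = _smoothing_loss_t(logits, y[i], loss_config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergence at epoch {epoch}: loss={loss.data!r}; "
                    f"state dump: {[(k, float(np.abs(v.data).max())) for k, v in net.params.items()][:8]}")
            loss.backward()
            losses.append(float(loss.data))
            if accum is None:
                accum = {k: np.array(net.params[k].grad)
                         for k in trainable if net.params[k].grad is not None}
            else:
                for k in trainable:
                    g = net.params[k].grad
                    if g is not None:
                        accum[k] = accum.get(k, 0) + g
            n_in_batch += 1
            if n_in_batch == schedule.batch_size:
                opt.step({k: v / n_in_batch for k, v in accum.items()})
                accum, n_in_batch = None, 0
        if n_in_batch:
            opt.step({k: v / n_in_batch for k, v in accum.items()})
        val_probs = predict_cohort(net, cache if cache is not None else bags,
                                   X, va, mode=mode)
        metric = _macro_ovr_auc(val_probs, y[va])
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_metric": metric})
        if verbose:
            log.info("epoch %d loss %.4f val %.4f", epoch, np.mean(losses), metric)
        if metric > best_metric + 1e-6:
            best_metric, best_net, since_best = metric, net.copy(), 0
        else:
            since_best += 1
            if since_best >= schedule.patience:
                break
    return best_net, pd.DataFrame(rows)
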