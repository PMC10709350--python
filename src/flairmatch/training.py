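"""Cross-validation splits, losses, and the optimization loops.

The evaluation protocol uses 4-fold cross-validation with train/validation/
test ratios of 56 %/19 %/25 % and pairwise-disjoint test sets; set sizes are
floored and the remainder goes to the training set, which for a 489-patient
cohort yields the 122-patient test folds.  Class imbalance is handled by
weighting the binary cross-entropy with

    w_c = N_total / (2 * N_c),

which balances the weighted class mass exactly (w0*N0 = w1*N1 = N_total/2).
Autoencoder-regularized training combines losses as

    L = alpha * L_bc + (1 - alpha) * L_mse.

Optimization is SGD with Nesterov momentum; runs are deterministic given the
master seed (one seed fans out to shuffle/dropout/noise streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .model import AERegNet, CAENet, ClassifierNet
from .nn import SGD

_EPS = 1e-7  # probability clamp for log terms


# -- cross-validation splits ------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Per-fold train/validation/test partition of the cohort."""

    folds: tuple[dict, ...]
    ratios: tuple[float, float, float]
    n_folds: int
    seed: int

    def __iter__(self):
        return iter(self.folds)


def make_splits(patient_ids, seed: int,
                ratios: tuple[float, float, float] = (0.56, 0.19, 0.25),
                n_folds: int = 4, labels=None, stratify: bool = False) -> SplitPlan:
    """Draw the cross-validation plan.

    Test sets are ``n_folds`` disjoint blocks of ``floor(n * ratios[2])``
    patients from one global shuffle; within each fold the validation set is
    the next ``floor(n * ratios[1])`` patients in rotated order and everything
    else (including the global remainder) trains.  ``stratify=True`` applies
    the same scheme per class and merges.
    """
    ids = np.asarray(patient_ids)
    n = ids.size
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {n}")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")

    if stratify:
        if labels is None:
            raise ValueError("stratify=True requires labels")
        labels = np.asarray(labels)
        plans = []
        for cls in np.unique(labels):
            sub = ids[labels == cls]
            plans.append(make_splits(sub, seed=seed + int(cls) + 1,
                                     ratios=ratios, n_folds=n_folds))
        folds = []
        for f in range(n_folds):
            folds.append({
                part: np.concatenate([p.folds[f][part] for p in plans])
                for part in ("train", "val", "test")
            })
        return SplitPlan(folds=tuple(folds), ratios=tuple(ratios),
                         n_folds=n_folds, seed=seed)

    rng = np.random.default_rng(seed)
    perm = ids[rng.permutation(n)]
    n_test = int(np.floor(n * ratios[2]))
    n_val = int(np.floor(n * ratios[1]))
    folds = []
    for f in range(n_folds):
        test = perm[f * n_test:(f + 1) * n_test]
        rest = np.concatenate([perm[(f + 1) * n_test:], perm[:f * n_test]])
        val = rest[:n_val]
        train = rest[n_val:]
        assert len(train) + len(val) + len(test) == n
        folds.append({"train": train, "val": val, "test": test})
    return SplitPlan(folds=tuple(folds), ratios=tuple(ratios), n_folds=n_folds, seed=seed)


# -- losses -----------------------------------------------------------------

def class_weights(labels) -> tuple[float, float]:
    """Inverse-prevalence weights w_c = N_total / (2 * N_c)."""
    y = np.asarray(labels).astype(int)
    n0 = int(np.sum(y == 0))
    n1 = int(np.sum(y == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = n0 + n1
    return n / (2.0 * n0), n / (2.0 * n1)


def weighted_bce(scores, labels, weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Class-weighted binary cross-entropy (mean over samples).

    Scores at exactly 0 or 1 are clamped to ``1e-7`` before the log.
    """
    s = np.clip(np.asarray(scores, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels).astype(float)
    w0, w1 = weights
    w = np.where(y == 1, w1, w0)
    return float(np.mean(-w * (y * np.log(s) + (1.0 - y) * np.log(1.0 - s))))


def combined_loss(bce: float, mse: float, alpha: float) -> float:
    """L = alpha * L_bc + (1 - alpha) * L_mse."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * bce + (1.0 - alpha) * mse


def _bce_on_logits(logits, y, w) -> tuple[float, np.ndarray]:
    """Numerically stable weighted BCE and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    # log(1 + exp(-|z|)) formulation
    loss = w * (np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - y * z)
    grad = w * (expit(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


# -- training loops ---------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization hyperparameters (SGD with Nesterov momentum)."""

    lr: float = 1e-2
    momentum: float = 0.9
    nesterov: bool = True
    epochs: int = 20
    batch_size: int = 8
    alpha: float = 1.0            # loss weighting; 1.0 = pure classification
    class_weighted: bool = True
    patience: int | None = None   # early stopping on validation loss
    shuffle: bool = True
    history: dict = field(default_factory=dict, repr=False)


def _batches(n, batch_size, rng, shuffle):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_classifier(net: ClassifierNet | AERegNet, X, y, cfg: TrainConfig,
                     X_val=None, y_val=None, seed: int = 0) -> dict:
    """Train a classifier (optionally AE-regularized) and keep the best
    validation checkpoint.  Returns the per-epoch history; the network is left
    holding the best weights (final weights if no validation set)."""
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    ae_reg = isinstance(net, AERegNet)
    if not ae_reg and cfg.alpha != 1.0:
        raise ValueError("alpha < 1 requires an AE-regularized model")

    ss = np.random.SeedSequence(seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    net.set_dropout_rng(dropout_rng)
    opt = SGD(net.parameters(), lr=cfg.lr, momentum=cfg.momentum, nesterov=cfg.nesterov)

    if cfg.class_weighted:
        w0, w1 = class_weights(y)
    else:
        w0 = w1 = 1.0
    wvec = np.where(y == 1, w1, w0)

    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _batches(n, cfg.batch_size, shuffle_rng, cfg.shuffle):
            xb, yb, wb = X[idx], y[idx], wvec[idx]
            opt.zero_grad()
            if ae_reg:
                logit, recon = net.forward(xb, train=True)
                bce, dlogit = _bce_on_logits(logit, yb, wb)
                diff = recon - xb
                mse = float(np.mean(diff ** 2))
                drecon = (2.0 * (1.0 - cfg.alpha) / diff.size) * diff
                loss = combined_loss(bce, mse, cfg.alpha)
                net.backward(cfg.alpha * dlogit, drecon)
            else:
                logit = net.forward(xb, train=True)
                loss, dlogit = _bce_on_logits(logit, yb, wb)
                net.backward(dlogit)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}; "
                    f"last finite losses: {losses[-3:]}")
            losses.append(loss)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))

        if X_val is not None:
            vl = _eval_loss(net, X_val, y_val, (w0, w1), cfg, ae_reg)
            history["val_loss"].append(vl)
            if vl < best[0]:
                best = (vl, net.state_dict())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if cfg.patience is not None and bad_epochs > cfg.patience:
                    break
    if best[1] is not None:
        net.load_state_dict(best[1])
    cfg.history = history
    return history


def _eval_loss(net, X_val, y_val, weights, cfg, ae_reg) -> float:
    X_val = np.asarray(X_val, dtype=np.float32)
    y_val = np.asarray(y_val).astype(int)
    w0, w1 = weights
    wv = np.where(y_val == 1, w1, w0)
    losses = []
    sizes = []
    for i in range(0, X_val.shape[0], cfg.batch_size):
        xb = X_val[i:i + cfg.batch_size]
        yb = y_val[i:i + cfg.batch_size]
        wb = wv[i:i + cfg.batch_size]
        if ae_reg:
            logit, recon = net.forward(xb, train=False)
            bce, _ = _bce_on_logits(logit, yb, wb)
            loss = combined_loss(bce, float(np.mean((recon - xb) ** 2)), cfg.alpha)
        else:
            logit = net.forward(xb, train=False)
            loss, _ = _bce_on_logits(logit, yb, wb)
        losses.append(loss)
        sizes.append(len(yb))
    return float(np.average(losses, weights=sizes))


def pretrain_cae(net: CAENet, X, cfg: TrainConfig, seed: int = 0) -> dict:
    """Unsupervised reconstruction pre-training on labeled + unlabeled pairs."""
    X = np.asarray(X, dtype=np.float32)
    n = X.shape[0]
    ss = np.random.SeedSequence(seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    net.set_dropout_rng(dropout_rng)
    opt = SGD(net.parameters(), lr=cfg.lr, momentum=cfg.momentum, nesterov=cfg.nesterov)
    history = {"train_loss": []}
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _batches(n, cfg.batch_size, shuffle_rng, cfg.shuffle):
            xb = X[idx]
            opt.zero_grad()
            recon = net.forward(xb, train=True)
            diff = recon - xb
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"pre-training diverged at epoch {epoch}")
            net.backward((2.0 / diff.size) * diff)
            losses.append(loss)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
    return history


def predict_scores(net, X, batch_size: int = 8) -> np.ndarray:
    """Sigmoid scores in [0, 1], batched to bound memory."""
    X = np.asarray(X, dtype=np.float32)
    out = []
    for i in range(0, X.shape[0], batch_size):
        out.append(net.predict_proba(X[i:i + batch_size]))
    return np.concatenate(out) if out else np.empty(0)
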