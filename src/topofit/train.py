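"""Training frameworks: supervised pre-training, semi-supervised topological
training, and per-item post-processing adaptation.

Three regimes, all driven by the same gradient plumbing (each loss supplies
dL/dS in closed form and the predictor backpropagates it to its weights):

* **Supervised** — minimise the soft Dice loss (or MSE in denoising mode) on
  labelled pairs, evaluating a validation metric every ``val_interval``
  epochs and stopping once it has failed to improve ``patience`` times; the
  best-validation weights are returned.

* **Semi-supervised** — alternate one labelled batch backpropagating the
  Dice loss with one unlabelled batch backpropagating ``lam`` times the
  mean topological loss, whose Betti prior is supplied per item.  The
  unlabelled items contribute a training signal without any pixel labels.
  With ``lam = 0`` the unlabelled stream is skipped entirely, so the run is
  bit-identical to continued supervised training under the same seed
  (labelled and unlabelled batch sampling use separate seeded streams).

* **Post-processing** — for a single test item, clone the trained weights
  and minimise ``mean((S - S0)^2) + lam * L_topo(S)`` where ``S0`` is the
  frozen prediction of the original network: the minimal change to the
  output that corrects its topology.  The original predictor is never
  touched; the weights achieving the best objective are returned.

The optimiser is adaptive-moment gradient descent throughout.  Barcodes are
recomputed from scratch at every step, since the critical pixels migrate as
the probability map changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .loss import TopologicalPrior, topo_loss_on_field
from .models import Adam, Predictor, clone_predictor
from .synthetic import SyntheticSample

__all__ = [
    "TrainConfig",
    "soft_dice_loss",
    "train_supervised",
    "train_semisupervised",
    "postprocess_adapt",
    "early_stop_index",
]

PriorFn = Callable[[SyntheticSample], TopologicalPrior]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by the training frameworks.

    ``lam`` is the topological-loss weight; ``batch_size = 0`` means one
    full labelled batch per epoch.  ``steps``/``postproc_lr`` apply to the
    post-processing framework only.
    """

    lam: float = 0.01
    lr: float = 1e-3
    batch_size: int = 0
    unlabelled_batch_size: int = 5
    epochs: int = 200
    val_interval: int = 10
    patience: int = 5
    steps: int = 250
    postproc_lr: float = 3e-4
    loss: str = "dice"  # "dice" or "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# ---------------------------------------------------------------------------
# Pixelwise losses (value + closed-form gradient)
# ---------------------------------------------------------------------------

_DICE_EPS = 1e-6


def soft_dice_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Soft Dice loss ``1 - (2 sum(p t) + eps) / (sum p + sum t + eps)``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    num = 2.0 * float((pred * target).sum()) + _DICE_EPS
    den = float(pred.sum() + target.sum()) + _DICE_EPS
    return 1.0 - num / den


def _soft_dice_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    num = 2.0 * float((pred * target).sum()) + _DICE_EPS
    den = float(pred.sum() + target.sum()) + _DICE_EPS
    return -(2.0 * target * den - num) / den**2


def _mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def _mse_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return 2.0 * (pred - target) / pred.size


def _hard_dice(pred: np.ndarray, target: np.ndarray, thr: float = 0.5) -> float:
    a = pred >= thr
    b = target >= thr
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def early_stop_index(val_metrics: Sequence[float], patience: int) -> int | None:
    """Index of the validation evaluation at which training stops.

    The rule: stop as soon as the metric has failed to improve on the best
    seen value for ``patience`` consecutive evaluations.  Returns ``None``
    if the sequence never triggers the rule.
    """
    best = -np.inf
    bad = 0
    for i, m in enumerate(val_metrics):
        if m > best:
            best = m
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                return i
    return None


# ---------------------------------------------------------------------------
# The shared epoch engine
# ---------------------------------------------------------------------------


def _val_metric(pred: Predictor, val: Sequence[SyntheticSample], mode: str) -> float:
    scores = []
    for s in val:
        S = pred.predict(s.image)
        if mode == "dice":
            scores.append(_hard_dice(S, s.target))
        else:
            scores.append(-_mse_loss(S, s.target))
    return float(np.mean(scores))


def _run_training(
    pred: Predictor,
    labelled: Sequence[SyntheticSample],
    unlabelled: Sequence[SyntheticSample] | None,
    val: Sequence[SyntheticSample],
    prior_fn: PriorFn | None,
    cfg: TrainConfig,
) -> tuple[Predictor, dict]:
    if not labelled:
        raise ValueError("labelled set is empty")
    if not val:
        raise ValueError("validation set is empty")
    if any(s.target is None for s in labelled) or any(s.target is None for s in val):
        raise ValueError("labelled and validation samples must carry targets")
    mode = cfg.loss
    if mode not in ("dice", "mse"):
        raise ValueError(f"unknown loss mode {cfg.loss!r}")
    loss_fn, grad_fn = (
        (soft_dice_loss, _soft_dice_grad) if mode == "dice" else (_mse_loss, _mse_grad)
    )
    use_topo = bool(unlabelled) and cfg.lam > 0
    # separate streams so the labelled schedule is unaffected by whether the
    # unlabelled stream runs at all (lam = 0 <=> pure supervised, bit-for-bit)
    rng_lab = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    rng_unlab = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    opt = Adam(pred.parameters(), lr=cfg.lr)
    history: dict = {"epoch": [], "sup_loss": [], "topo_loss": [],
                     "val_epoch": [], "val_metric": []}
    best_state = pred.state_dict()
    best_metric = -np.inf
    bad = 0
    bs = cfg.batch_size if cfg.batch_size > 0 else len(labelled)

    for epoch in range(1, cfg.epochs + 1):
        order = rng_lab.permutation(len(labelled))
        sup_losses: list[float] = []
        topo_losses: list[float] = []
        for start in range(0, len(labelled), bs):
            batch = [labelled[i] for i in order[start:start + bs]]
            pred.zero_grad()
            acc = 0.0
            for s in batch:
                S = pred.forward(s.image)
                acc += loss_fn(S, s.target)
                pred.backward(grad_fn(S, s.target) / len(batch))
            opt.step()
            sup_losses.append(acc / len(batch))

            if use_topo:
                k = min(cfg.unlabelled_batch_size, len(unlabelled))
                pick = rng_unlab.choice(len(unlabelled), size=k, replace=False)
                pred.zero_grad()
                acc_t = 0.0
                for i in pick:
                    s = unlabelled[i]
                    S = pred.forward(s.image)
                    rep = topo_loss_on_field(S, prior_fn(s))
                    acc_t += rep.total
                    pred.backward(cfg.lam * rep.gradient_array(S.shape) / k)
                opt.step()
                topo_losses.append(acc_t / k)

        history["epoch"].append(epoch)
        history["sup_loss"].append(float(np.mean(sup_losses)))
        history["topo_loss"].append(float(np.mean(topo_losses)) if topo_losses else None)

        if epoch % cfg.val_interval == 0 or epoch == cfg.epochs:
            metric = _val_metric(pred, val, mode)
            history["val_epoch"].append(epoch)
            history["val_metric"].append(metric)
            if metric > best_metric:
                best_metric = metric
                best_state = pred.state_dict()
                bad = 0
            else:
                bad += 1
                if bad >= cfg.patience:
                    break

    pred.load_state_dict(best_state)
    history["best_val_metric"] = best_metric
    return pred, history


def train_supervised(
    pred: Predictor,
    labelled: Sequence[SyntheticSample],
    val: Sequence[SyntheticSample],
    cfg: TrainConfig,
) -> tuple[Predictor, dict]:
    """Supervised training with early stopping; returns best-validation weights."""
    return _run_training(pred, labelled, None, val, None, cfg)


def train_semisupervised(
    pred: Predictor,
    labelled: Sequence[SyntheticSample],
    unlabelled: Sequence[SyntheticSample],
    val: Sequence[SyntheticSample],
    prior_fn: PriorFn,
    cfg: TrainConfig,
) -> tuple[Predictor, dict]:
    """Semi-supervised training: Dice on labelled, topological loss on unlabelled.

    ``pred`` should already be supervised-pretrained so its predictions on
    the unlabelled items are good enough for the topological loss to help.
    An empty unlabelled set degenerates to supervised training (warned).
    """
    if not unlabelled:
        warnings.warn("unlabelled set is empty; training degenerates to supervised")
        return _run_training(pred, labelled, None, val, None, cfg)
    return _run_training(pred, labelled, unlabelled, val, prior_fn, cfg)


def postprocess_adapt(
    pred: Predictor,
    image: np.ndarray,
    prior: TopologicalPrior,
    cfg: TrainConfig,
) -> tuple[Predictor, np.ndarray, dict]:
    """Per-item topological adaptation of a trained predictor.

    Clones ``pred``, freezes its output on ``image`` as the anchor ``S0``,
    and runs ``cfg.steps`` optimiser steps on the objective
    ``mean((S - S0)^2) + lam * L_topo(S)``.  Returns the adapted clone
    (weights with the best objective seen), its probability map, and a
    history of objective values.  ``pred`` itself is left unchanged.
    """
    if cfg.lam < 0:
        raise ValueError("lam must be >= 0")
    anchor = pred.predict(np.asarray(image, dtype=np.float64))
    adapted = clone_predictor(pred)
    opt = Adam(adapted.parameters(), lr=cfg.postproc_lr)
    history: dict = {"objective": [], "proximity": [], "topo": []}
    best = (np.inf, adapted.state_dict(), anchor)
    V = anchor.size
    for _ in range(cfg.steps):
        S = adapted.forward(image)
        prox = float(np.mean((S - anchor) ** 2))
        dS = 2.0 * (S - anchor) / V
        topo = 0.0
        if cfg.lam > 0:
            rep = topo_loss_on_field(S, prior)
            topo = rep.total
            dS = dS + cfg.lam * rep.gradient_array(S.shape)
        objective = prox + cfg.lam * topo
        history["objective"].append(objective)
        history["proximity"].append(prox)
        history["topo"].append(topo)
        if objective < best[0]:
            best = (objective, adapted.state_dict(), S.copy())
        adapted.zero_grad()
        adapted.backward(dS)
        opt.step()
    adapted.load_state_dict(best[1])
    history["best_objective"] = best[0]
    return adapted, best[2], history
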