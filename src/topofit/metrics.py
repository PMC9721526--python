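"""Evaluation metrics: Dice overlap and topological correctness.

A prediction is *topologically correct* when, thresholded at 0.5, its
Betti numbers match the prior in every dimension the prior specifies —
computed by the Betti oracle directly on the thresholded set, with no
persistence involved.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cubical import betti_at_threshold
from .loss import TopologicalPrior
from .models import Predictor
from .synthetic import SyntheticSample

__all__ = ["dice_score", "topological_correctness", "evaluate", "EvalReport"]


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` of two binary masks.

    Defined as 1 when both masks are empty.  Non-boolean inputs are
    interpreted as masks via ``>= 0.5``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    am = a if a.dtype == bool else a >= 0.5
    bm = b if b.dtype == bool else b >= 0.5
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


def topological_correctness(
    field: np.ndarray, prior: TopologicalPrior, threshold: float = 0.5
) -> bool:
    """True iff the thresholded field has the prior's Betti numbers in every dim."""
    return all(
        betti_at_threshold(field, threshold, k) == want
        for k, want in prior.desired.items()
    )


@dataclass
class EvalReport:
    """Per-item Dice and topology flags plus their aggregates."""

    items: list[dict]
    mean_dice: float
    proportion_topologically_correct: float
    threshold: float = 0.5

    def to_json(self, path: str | os.PathLike | None = None) -> dict:
        obj = {
            "mean_dice": self.mean_dice,
            "proportion_topologically_correct": self.proportion_topologically_correct,
            "threshold": self.threshold,
            "items": self.items,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        return obj

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["index", "dice", "betti", "topo_correct"])
            w.writeheader()
            for it in self.items:
                w.writerow({**it, "betti": " ".join(map(str, it["betti"]))})


def evaluate(
    pred: Predictor,
    test: Sequence[SyntheticSample],
    prior_fn: Callable[[SyntheticSample], TopologicalPrior],
    threshold: float = 0.5,
) -> EvalReport:
    """Evaluate a predictor on a test set: per-item Dice, Betti numbers at the
    threshold, and topological correctness; aggregates are plain means."""
    if not test:
        raise ValueError("test set is empty")
    items = []
    dices = []
    flags = []
    for idx, s in enumerate(test):
        S = pred.predict(s.image)
        prior = prior_fn(s)
        betti = tuple(
            betti_at_threshold(S, threshold, k) for k in sorted(prior.desired)
        )
        ok = all(betti_at_threshold(S, threshold, k) == want
                 for k, want in prior.desired.items())
        dice = float("nan")
        if s.target is not None:
            dice = dice_score(S, s.target)
            dices.append(dice)
        flags.append(bool(ok))
        items.append({"index": idx, "dice": dice, "betti": betti, "topo_correct": ok})
    return EvalReport(
        items=items,
        mean_dice=float(np.mean(dices)) if dices else float("nan"),
        proportion_topologically_correct=float(np.mean(flags)),
        threshold=threshold,
    )
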