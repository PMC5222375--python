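"""Repeated k-fold cross-validation of genomic-prediction models.

Accuracy is the Pearson correlation between pooled out-of-fold
predictions and observed phenotypes, computed per repetition over a
fresh seeded random partition into near-equal folds.  Models are refit
(including any internal hyperparameter tuning) on every training split,
so no test-fold information leaks into fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold


@dataclass
class CvResult:
    """Accuracy distribution from repeated k-fold cross-validation."""

    model_tag: str
    trait: str
    n_folds: int
    n_reps: int
    accuracies: np.ndarray
    master_seed: int | None
    flagged_reps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        finite = self.accuracies[np.isfinite(self.accuracies)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("accuracies must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.accuracies, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_tag,
                "trait": self.trait,
                "repetition": np.arange(1, len(self.accuracies) + 1),
                "accuracy": self.accuracies,
            }
        )

    def summary(self) -> dict:
        return {
            "model": self.model_tag,
            "trait": self.trait,
            "n_folds": self.n_folds,
            "n_reps": self.n_reps,
            "mean_accuracy": self.mean,
            "sd_accuracy": self.sd,
            "seed": self.master_seed,
        }


def kfold_accuracy(
    model,
    G,
    y,
    n_folds: int = 10,
    n_reps: int = 500,
    seed: int | None = None,
    trait: str = "trait",
    model_tag: str | None = None,
    pooled: bool = True,
) -> CvResult:
    """Repeated k-fold cross-validated Pearson accuracy of a model.

    ``model`` is any unfitted estimator with fit/predict; if it exposes
    a ``seed`` parameter the per-repetition seed is propagated so reruns
    with the same master seed are identical.

    ``pooled=True`` correlates the pooled out-of-fold predictions with
    the observations (stable with small folds, but biased negative for
    an uninformative model because fold predictions track the training
    mean); ``pooled=False`` averages within-fold correlations instead
    (unbiased under the null, noisier).
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError("need at least 2 samples per fold")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    rep_seeds = (rep_seeds % (2**31 - 1)).astype(np.int64)

    accuracies = np.empty(n_reps)
    flagged: list[int] = []
    for rep in range(n_reps):
        rs = int(rep_seeds[rep])
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
        preds = np.empty(n)
        fold_accs = []
        for fold_i, (train, test) in enumerate(kf.split(G)):
            est = clone(model)
            if "seed" in est.get_params():
                est.set_params(seed=rs + fold_i)
            est.fit(G[train], y[train])
            preds[test] = est.predict(G[test])
            if not pooled:
                if np.std(y[test]) > 0 and np.std(preds[test]) > 0:
                    fold_accs.append(float(np.corrcoef(preds[test], y[test])[0, 1]))
        if pooled:
            if np.std(y) == 0.0 or np.std(preds) == 0.0:
                accuracies[rep] = np.nan
                flagged.append(rep)
            else:
                accuracies[rep] = float(np.corrcoef(preds, y)[0, 1])
        else:
            if fold_accs:
                accuracies[rep] = float(np.mean(fold_accs))
                if len(fold_accs) < n_folds:
                    flagged.append(rep)
            else:
                accuracies[rep] = np.nan
                flagged.append(rep)
    tag = model_tag or getattr(model, "_tag", type(model).__name__)
    return CvResult(tag, trait, n_folds, n_reps, accuracies, seed, flagged)
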