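"""Patient-level cross-validation and the HIZ comparison arm.

Discs from one patient are never split between training and validation:
folds are assigned at patient level, with fissure-positive discs spread
as evenly across folds as patient granularity allows (randomized greedy
bin-packing on each patient's positive-disc count).  Every disc is
scored exactly once, by an ensemble whose training folds exclude its
patient; feature standardization statistics are estimated on the
training folds only.

The conventional-marker arm simply predicts "outer annular fissure" for
any disc carrying a high-intensity-zone (HIZ) flag, which is how the
marker is used radiologically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import TrainConfig, EnsembleModel, train_ensemble, \
    ensemble_predict, classify

__all__ = [
    "FoldAssignment",
    "dichotomize_ddd",
    "make_folds",
    "run_cv",
    "hiz_marker_predictions",
]


def dichotomize_ddd(grade: int) -> bool:
    """Outer-annular-fissure label from a Dallas discogram grade (0-3).

    Grades 2-3 (fissure reaching the outer third of the annulus) are
    positive; grades 0-1 negative.
    """
    g = int(grade)
    if g not in (0, 1, 2, 3):
        raise ValueError(f"DDD grade must be 0..3, got {grade}")
    return g >= 2


@dataclass(frozen=True)
class FoldAssignment:
    """Patient -> fold mapping for k-fold patient-level cross-validation."""

    k: int
    mapping: Dict[str, int]
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.mapping[patient_id]

    def disc_folds(self, manifest: pd.DataFrame) -> np.ndarray:
        return manifest["patient_id"].map(self.mapping).to_numpy()


def make_folds(manifest: pd.DataFrame, k: int = 10, seed: int = 0
               ) -> FoldAssignment:
    """Assign patients to ``k`` folds, balancing fissure-positive discs.

    Patients are shuffled (seeded), ordered by descending positive-disc
    count, and each is assigned to the fold currently holding the fewest
    positives; ties break on total disc count, then fold index.  The
    per-fold positive spread is therefore bounded by the largest single
    patient's positive count.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (one fold leaves no training data)")
    patients = manifest.groupby("patient_id").agg(
        n_pos=("fissure_present", "sum"), n=("fissure_present", "size"))
    if k > len(patients):
        raise ValueError(f"k={k} exceeds number of patients {len(patients)}")
    rng = np.random.default_rng(seed)
    order = patients.index.to_numpy().copy()
    rng.shuffle(order)
    patients = patients.loc[order]
    patients = patients.sort_values("n_pos", ascending=False, kind="stable")

    fold_pos = np.zeros(k)
    fold_n = np.zeros(k)
    mapping: Dict[str, int] = {}
    for pid, row in patients.iterrows():
        key = list(zip(fold_pos, fold_n, range(k)))
        f = min(range(k), key=lambda i: key[i])
        mapping[str(pid)] = f
        fold_pos[f] += row["n_pos"]
        fold_n[f] += row["n"]
    return FoldAssignment(k=k, mapping=mapping, seed=seed)


def run_cv(features: pd.DataFrame, manifest: pd.DataFrame,
           folds: FoldAssignment,
           cfg: Optional[TrainConfig] = None,
           ensemble_size: int = 50,
           base_seed: int = 0,
           threshold: float = 0.5,
           paper_faithful: bool = False,
           return_models: bool = False):
    """Out-of-fold predictions from patient-level k-fold cross-validation.

    ``features`` is indexed by disc_id (columns = feature ids in registry
    order); ``manifest`` supplies ``disc_id``, ``patient_id`` and
    ``fissure_present``.  For each fold a fresh ensemble is trained on
    the remaining folds and scores the held-out discs; standardization
    statistics never leak from held-out data.  With ``paper_faithful``
    the held-out fold itself is the early-stop set (the literal reading
    of the training protocol); the default carves an inner 20% split.

    Returns a DataFrame (disc_id, patient_id, fold, prob, pred, label),
    plus the per-fold models when ``return_models``.
    """
    cfg = cfg or TrainConfig()
    # canonical disc order: predictions must not depend on row order
    man = manifest.set_index("disc_id").sort_index()
    X = features.loc[man.index].to_numpy(dtype=float)
    y = man["fissure_present"].to_numpy(dtype=int)
    disc_fold = man["patient_id"].map(folds.mapping).to_numpy()
    if np.any(pd.isna(disc_fold)):
        raise ValueError("manifest contains patients missing from folds")

    rows = []
    models: Dict[int, EnsembleModel] = {}
    for f in range(folds.k):
        held = disc_fold == f
        if not held.any():
            raise ValueError(f"fold {f} holds no discs")
        tr = ~held
        kwargs = {}
        if paper_faithful:
            kwargs = {"X_val": X[held], "y_val": y[held]}
        model = train_ensemble(X[tr], y[tr], size=ensemble_size, cfg=cfg,
                               base_seed=base_seed + 10_000 * f, **kwargs)
        models[f] = model
        probs = ensemble_predict(X[held], model)
        preds = classify(probs, threshold)
        for disc_id, p, pr, lab in zip(man.index[held], probs, preds, y[held]):
            rows.append({"disc_id": disc_id,
                         "patient_id": man.loc[disc_id, "patient_id"],
                         "fold": f, "prob": float(p), "pred": bool(pr),
                         "label": bool(lab)})
    result = pd.DataFrame(rows).set_index("disc_id").loc[man.index].reset_index()
    if return_models:
        return result, models
    return result


def hiz_marker_predictions(manifest: pd.DataFrame) -> pd.Series:
    """Predict fissure presence from the HIZ flag alone.

    A disc is called positive iff it carries a ventral or dorsal HIZ;
    lateral fissures have no HIZ category and contribute nothing.
    """
    if "hiz_flag" not in manifest.columns:
        raise ValueError("manifest has no hiz_flag column")
    if manifest["hiz_flag"].isna().any():
        raise ValueError("hiz_flag missing for some discs")
    return manifest.set_index("disc_id")["hiz_flag"].astype(bool)
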