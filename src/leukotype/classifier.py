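"""Multiclass SVM subtype classifier over rank profiles.

An RBF-kernel support vector machine (one-vs-one voting, the behaviour of
the libsvm backend shared by sklearn's ``SVC`` and R's ``e1071::svm``) is
trained on rank profiles.  The soft-margin cost C and kernel width gamma are
chosen by stratified k-fold cross-validation (default 10-fold) over a coarse
power-of-two grid; ties between grid points with equal CV accuracy resolve
to the smallest C, then the smallest gamma.

Because the features are within-sample ranks bounded in [1, 57], no feature
scaling is applied — gamma is always an explicit number, never sklearn's
data-dependent ``"scale"`` — and a model trained on one platform applies
unchanged to profiles from any other platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DimensionError, ModelLoadError, ValidationError
from .io import SampleLabels
from .ranking import MarkerPanel, RankProfiles

#: Coarse power-of-two hyperparameter grid: C in 2^-5..2^15, gamma in 2^-15..2^3.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))

_MODEL_FORMAT = "leukotype-subtype-model"
_MODEL_VERSION = 1


@dataclass
class CVReport:
    """Cross-validation record of the hyperparameter search."""

    grid: pd.DataFrame  # columns: C, gamma, cv_accuracy
    best_C: float
    best_gamma: float
    best_accuracy: float
    folds: int

    def to_csv(self, path: str | Path) -> None:
        out = self.grid.copy()
        out["best"] = (out["C"] == self.best_C) & (out["gamma"] == self.best_gamma)
        out.to_csv(path, index=False, float_format="%.10g")


@dataclass
class SubtypeModel:
    """Fitted subtype classifier plus everything needed to re-apply it."""

    panel: MarkerPanel
    classes: tuple[str, ...]
    C: float
    gamma: float
    kernel: str
    seed: int
    training_platform: str = ""
    svc: SVC = field(default=None, repr=False)


def _cv_splits(y: np.ndarray, folds: int, seed: int) -> list[tuple]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def train(
    profiles: RankProfiles,
    labels: SampleLabels,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
) -> tuple[SubtypeModel, CVReport]:
    """Select (C, gamma) by stratified CV, then refit on all samples.

    The same fold partition is reused for every grid point, so CV accuracies
    are comparable across the grid and the whole procedure is a pure
    function of (data, grid, folds, seed).  A class with fewer samples than
    folds triggers a warning and a reduced fold count rather than an error.
    """
    # canonical sample order: CV outcome is a function of the labeled set,
    # not of the order samples happen to arrive in
    sample_ids = sorted(profiles.sample_ids)
    missing = [s for s in sample_ids if s not in labels.labels]
    if missing:
        raise ValidationError(f"samples without labels: {missing}")
    X = profiles.ranks[sample_ids].to_numpy().T
    y = np.array([labels[s] for s in sample_ids])
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValidationError("training requires at least two subtype classes")
    min_class = int(pd.Series(y).value_counts().min())
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples < {folds} folds; "
            f"reducing to {max(2, min_class)} folds for stratification",
            stacklevel=2,
        )
        folds = max(2, min_class)
    splits = _cv_splits(y, folds, seed)

    rows = []
    best = (-1.0, None, None)
    for C in c_grid:
        for gamma in gamma_grid:
            accs = []
            for tr, te in splits:
                clf = SVC(C=C, gamma=gamma, kernel=kernel, random_state=seed)
                clf.fit(X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
            acc = float(np.mean(accs))
            rows.append({"C": float(C), "gamma": float(gamma), "cv_accuracy": acc})
            if acc > best[0]:  # strict: earlier (smaller C, then gamma) wins ties
                best = (acc, float(C), float(gamma))
    report = CVReport(
        grid=pd.DataFrame(rows),
        best_C=best[1],
        best_gamma=best[2],
        best_accuracy=best[0],
        folds=folds,
    )
    svc = SVC(C=best[1], gamma=best[2], kernel=kernel, random_state=seed)
    svc.fit(X, y)
    model = SubtypeModel(
        panel=profiles.panel,
        classes=classes,
        C=best[1],
        gamma=best[2],
        kernel=kernel,
        seed=seed,
        training_platform="",
        svc=svc,
    )
    return model, report


def predict(model: SubtypeModel, profiles: RankProfiles) -> dict[str, str]:
    """Predict one subtype per sample.

    Each prediction depends only on that sample's 57 rank values; no cohort
    context enters, so a sample predicted alone gets the same label as the
    same sample predicted inside any batch.
    """
    if profiles.panel.genes != model.panel.genes:
        raise DimensionError(
            "rank profiles are not aligned to the model's marker panel order"
        )
    X = profiles.ranks.to_numpy().T
    pred = model.svc.predict(X)
    return dict(zip(profiles.sample_ids, (str(p) for p in pred)))


def save_model(model: SubtypeModel, path: str | Path) -> None:
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "panel": list(model.panel.genes),
        "classes": list(model.classes),
        "C": model.C,
        "gamma": model.gamma,
        "kernel": model.kernel,
        "seed": model.seed,
        "training_platform": model.training_platform,
        "svc": model.svc,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> SubtypeModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelLoadError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelLoadError(f"{path} is not a leukotype model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ModelLoadError(
            f"model version {payload.get('version')!r} unsupported "
            f"(expected {_MODEL_VERSION})"
        )
    return SubtypeModel(
        panel=MarkerPanel(tuple(payload["panel"])),
        classes=tuple(payload["classes"]),
        C=payload["C"],
        gamma=payload["gamma"],
        kernel=payload["kernel"],
        seed=payload["seed"],
        training_platform=payload.get("training_platform", ""),
        svc=payload["svc"],
    )
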