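"""Cross-validated regularized linear discriminant analysis.

The classifier follows the standard MVPA recipe for run-structured designs:
class means and a pooled within-class covariance are estimated on the
training runs, the covariance is regularized by adding 1% of its mean
diagonal to every diagonal element, and held-out patterns are assigned to
the class with the highest Gaussian likelihood under equal priors
(equivalently, minimal Mahalanobis distance).  Cross-validation leaves one
run out at a time, so with 4 conditions and 8 runs each dataset yields 32
test classifications, and accuracies are z-transformed with the normal
approximation to the binomial distribution for group-level inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_REG_FRACTION = 0.01
CHANCE_4CLASS = 0.25

__all__ = [
    "LDAModel",
    "ClassifierResult",
    "lda_train",
    "lda_classify",
    "crossval_accuracy",
    "accuracy_to_z",
    "accuracy_threshold",
    "behavioral_classifier",
    "behavioral_feature_grid",
]


@dataclass(frozen=True)
class LDAModel:
    means: np.ndarray  # (n_classes, n_voxels)
    covariance: np.ndarray  # regularized pooled within-class covariance
    classes: np.ndarray
    reg_fraction: float


@dataclass(frozen=True)
class ClassifierResult:
    accuracy: float
    n_test: int
    predictions: np.ndarray  # (n_test,) predicted class per test pattern
    true_labels: np.ndarray
    z: float


def lda_train(
    x: np.ndarray, y: np.ndarray, reg_fraction: float = DEFAULT_REG_FRACTION
) -> LDAModel:
    """Fit class means and the regularized pooled within-class covariance.

    The pooled covariance uses residuals from the training class means with
    denominator (observations - classes); regularization adds
    ``reg_fraction`` times the mean diagonal element to the diagonal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    resid = x - means[np.searchsorted(classes, y)]
    dof = x.shape[0] - len(classes)
    if dof < 1:
        raise ValueError("need at least 2 observations per class")
    sigma = resid.T @ resid / dof
    ridge = reg_fraction * np.mean(np.diag(sigma))
    sigma_reg = sigma + ridge * np.eye(sigma.shape[0])
    if np.all(sigma_reg == 0):
        raise ValueError("within-class covariance is exactly zero")
    return LDAModel(means, sigma_reg, classes, reg_fraction)


def lda_classify(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Assign each test pattern to the class with minimal Mahalanobis
    distance to its mean (= highest Gaussian likelihood under the shared
    covariance and equal priors).  Exact ties go to the lowest class index.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"test patterns have {x.shape[1]} voxels, model expects {model.means.shape[1]}"
        )
    # d2[i, c] = (x_i - mu_c)' Sigma^-1 (x_i - mu_c)
    diff = x[:, None, :] - model.means[None, :, :]  # (n, classes, p)
    sol = np.linalg.solve(
        model.covariance, diff.reshape(-1, diff.shape[-1]).T
    ).T.reshape(diff.shape)
    d2 = np.einsum("ncp,ncp->nc", diff, sol)
    return model.classes[np.argmin(d2, axis=1)]  # argmin keeps lowest index on ties


def accuracy_to_z(accuracy: float, n_test: int, chance: float) -> float:
    """z score of an accuracy under the binomial normal approximation."""
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must be in [0, 1]")
    if n_test < 1 or not 0 < chance < 1:
        raise ValueError("invalid n_test or chance")
    return (accuracy - chance) / np.sqrt(chance * (1 - chance) / n_test)


def accuracy_threshold(z_crit: float, n_test: int, chance: float) -> float:
    """Accuracy (%) corresponding to a critical z, truncated to one decimal.

    With z=1.64, 32 tests and 25% chance this yields the 37.5% within-subject
    significance threshold.
    """
    acc = chance + z_crit * np.sqrt(chance * (1 - chance) / n_test)
    return np.floor(1000.0 * acc) / 10.0


def crossval_accuracy(
    betas: np.ndarray, reg_fraction: float = DEFAULT_REG_FRACTION
) -> ClassifierResult:
    """Leave-one-run-out cross-validated classification of run-wise patterns.

    ``betas`` is (conditions, runs, voxels); each fold trains on all other
    runs and classifies the held-out run's condition patterns.
    """
    b = np.asarray(betas, dtype=float)
    k, n_runs, p = b.shape
    if n_runs < 2:
        raise ValueError("need at least 2 runs for cross-validation")
    labels = np.arange(k)
    preds, truth = [], []
    for test_run in range(n_runs):
        train_mask = np.arange(n_runs) != test_run
        x_train = b[:, train_mask, :].reshape(k * (n_runs - 1), p)
        y_train = np.repeat(labels, n_runs - 1)
        model = lda_train(x_train, y_train, reg_fraction)
        preds.append(lda_classify(model, b[:, test_run, :]))
        truth.append(labels)
    preds = np.concatenate(preds)
    truth = np.concatenate(truth)
    acc = float(np.mean(preds == truth))
    n_test = len(truth)
    return ClassifierResult(acc, n_test, preds, truth, accuracy_to_z(acc, n_test, 1.0 / k))


BEHAVIORAL_FEATURES = ("MT", "force", "error")


def behavioral_feature_grid(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Average MT, mean peak force, and error rate per condition and run.

    Returns (conditions x runs) arrays keyed by feature name; the grid must
    be complete (every condition observed in every run).
    """
    force_cols = [f"force_f{i}" for i in range(1, 6)]
    df = records.copy()
    df["force"] = df[force_cols].mean(axis=1)
    df["error_num"] = df["error"].astype(float)
    feats = {}
    for name, col in [("MT", "MT_ms"), ("force", "force"), ("error", "error_num")]:
        grid = df.pivot_table(index="condition", columns="run", values=col, aggfunc="mean")
        if grid.isna().any().any():
            raise ValueError("incomplete condition x run grid")
        feats[name] = grid.to_numpy()
    return feats


def behavioral_classifier(
    records: pd.DataFrame,
    features: tuple[str, ...] = BEHAVIORAL_FEATURES,
    reg_fraction: float = DEFAULT_REG_FRACTION,
) -> ClassifierResult:
    """Run the same cross-validated LDA on behavioral summary features.

    Each requested feature (a subset of MT, force, error) is averaged per
    condition and run, z-standardized across all condition-runs, and treated
    like a voxel.  Used to check whether pattern decoding could be explained
    by behavioral differences alone.
    """
    unknown = set(features) - set(BEHAVIORAL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    grids = behavioral_feature_grid(records)
    cols = []
    for name in features:
        g = grids[name]
        sd = g.std()
        if sd == 0:
            warnings.warn(f"feature {name!r} is constant; dropped", stacklevel=2)
            continue
        cols.append((g - g.mean()) / sd)
    if not cols:
        raise ValueError("no usable (non-constant) features")
    # (conditions, runs, n_features) pseudo-pattern array
    betas = np.stack(cols, axis=-1)
    return crossval_accuracy(betas, reg_fraction)
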