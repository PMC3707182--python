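"""Spatial dimensionality analysis of condition patterns.

With K=4 conditions, the grand-mean-centered class means span at most three
linear pattern components.  A classifier restricted to the top ``d`` most
informative components (ordered by singular value of the centered training
class means) reveals the geometry of the condition patterns: if patterns are
scaled versions of one pattern, one component suffices and extra components
only add noise; if patterns are spread evenly in pattern space, accuracy
grows with every added component.  Observed accuracy curves are interpreted
against simulations whose signal strength is calibrated so the simulated
accuracy at a chosen dimensionality matches the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mvpa import DEFAULT_REG_FRACTION, ClassifierResult, accuracy_to_z, lda_classify, lda_train
from .synthgen import make_ground_truth, simplex_coordinates

__all__ = [
    "AccuracyCurve",
    "centered_class_means",
    "reduced_dim_accuracy",
    "evenly_spaced_patterns",
    "simulate_accuracy_curves",
]


@dataclass(frozen=True)
class AccuracyCurve:
    """Mean accuracy of the d = 1, 2, 3 component classifiers."""

    accuracies: tuple[float, ...]  # index 0 -> d=1
    n_test: int
    matched_scale: float | None = None  # signal variance found by calibration
    achieved_match: float | None = None

    def accuracy(self, d: int) -> float:
        return self.accuracies[d - 1]


def centered_class_means(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Class means minus their grand mean; rank is at most n_classes - 1."""
    classes = np.unique(y)
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    return means - means.mean(axis=0)


def reduced_dim_accuracy(
    betas: np.ndarray, d: int, reg_fraction: float = DEFAULT_REG_FRACTION
) -> ClassifierResult:
    """Leave-one-run-out LDA restricted to the top-d pattern components.

    Per fold, the components are the right singular vectors of the centered
    training class means (ordered by singular value, i.e. by between-class
    signal); training and test patterns are projected onto them before the
    regularized LDA runs in the d-dimensional subspace.
    """
    b = np.asarray(betas, dtype=float)
    k, n_runs, p = b.shape
    if not 1 <= d <= k - 1:
        raise ValueError(f"d must be in 1..{k - 1}")
    labels = np.arange(k)
    preds, truth = [], []
    for test_run in range(n_runs):
        train_mask = np.arange(n_runs) != test_run
        x_train = b[:, train_mask, :].reshape(k * (n_runs - 1), p)
        y_train = np.repeat(labels, n_runs - 1)
        centered = centered_class_means(x_train, y_train)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        basis = vt[:d].T  # (p, d)
        model = lda_train(x_train @ basis, y_train, reg_fraction)
        preds.append(lda_classify(model, b[:, test_run, :] @ basis))
        truth.append(labels)
    preds = np.concatenate(preds)
    truth = np.concatenate(truth)
    acc = float(np.mean(preds == truth))
    return ClassifierResult(acc, len(truth), preds, truth, accuracy_to_z(acc, len(truth), 1.0 / k))


def evenly_spaced_patterns(
    k: int = 4, n_voxels: int = 160, rng_seed: int | None = None, scale: float = 1.0
) -> np.ndarray:
    """K patterns forming a regular simplex in a random (K-1)-dim subspace.

    The patterns sum to zero, all pairwise distances are equal, and their
    Gram matrix has K-1 equal nonzero eigenvalues.
    """
    if n_voxels < k - 1:
        raise ValueError("need at least K-1 voxels")
    rng = np.random.default_rng(rng_seed)
    q, _ = np.linalg.qr(rng.normal(size=(n_voxels, k - 1)))
    return scale * simplex_coordinates(k) @ q.T


def _simulated_curve(
    geometry: str,
    d_true: int,
    signal_var: float,
    n_voxels: int,
    n_runs: int,
    n_conditions: int,
    n_sims: int,
    seeds: np.ndarray,
    dims: tuple[int, ...],
    reg_fraction: float,
) -> np.ndarray:
    """Mean accuracy per classifier dimensionality over simulated datasets.

    Seeds are fixed per simulation index so the noise realizations are
    common across signal levels (accuracy is then monotone in signal_var,
    which keeps the bisection well behaved).
    """
    accs = np.zeros((len(dims), n_sims))
    for s in range(n_sims):
        gt = make_ground_truth(
            n_voxels,
            v_common=0.0,  # a shared offset does not affect the classifier
            v_specific=signal_var,
            v_run=0.0,
            v_trial=1.0,
            d=d_true,
            geometry=geometry,
            n_conditions=n_conditions,
            rng_seed=int(seeds[s]),
        )
        from .synthgen import simulate_betas

        betas = simulate_betas(gt, n_runs, rng_seed=int(seeds[s]) + 1)
        for j, d in enumerate(dims):
            accs[j, s] = reduced_dim_accuracy(betas, d, reg_fraction).accuracy
    return accs.mean(axis=1)


def simulate_accuracy_curves(
    geometry: str,
    d_true: int,
    n_voxels: int,
    n_runs: int,
    match_accuracy: float,
    match_dim: int = 3,
    n_sims: int = 50,
    rng_seed: int | None = None,
    n_conditions: int = 4,
    reg_fraction: float = DEFAULT_REG_FRACTION,
    tol: float = 0.005,
    max_iter: int = 40,
) -> AccuracyCurve:
    """Accuracy-matched simulation of the d = 1..K-1 classifier curve.

    Bisects on the sequence-specific signal variance (noise fixed at 1)
    until the mean simulated accuracy of the ``match_dim``-dimensional
    classifier equals ``match_accuracy`` within ``tol``, then reports the
    mean accuracies of all restricted classifiers at that signal level.
    """
    chance = 1.0 / n_conditions
    dims = tuple(range(1, n_conditions))
    n_test = n_conditions * n_runs
    if match_accuracy <= chance:
        warnings.warn(
            "match_accuracy at or below chance; returning flat chance curve",
            stacklevel=2,
        )
        return AccuracyCurve(tuple([chance] * len(dims)), n_test, 0.0, chance)
    if match_accuracy > 1:
        raise ValueError("match_accuracy must be at most 1")
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    j_match = dims.index(match_dim)

    def mean_acc(signal_var: float) -> np.ndarray:
        return _simulated_curve(
            geometry, d_true, signal_var, n_voxels, n_runs, n_conditions,
            n_sims, seeds, dims, reg_fraction,
        )

    lo, hi = 0.0, 1.0
    curve_hi = mean_acc(hi)
    guard = 0
    while curve_hi[j_match] < match_accuracy and guard < 20:
        lo, hi = hi, hi * 4
        curve_hi = mean_acc(hi)
        guard += 1
    best_curve, best_scale = curve_hi, hi
    for _ in range(max_iter):
        if abs(best_curve[j_match] - match_accuracy) <= tol:
            break
        mid = 0.5 * (lo + hi)
        curve = mean_acc(mid)
        best_curve, best_scale = curve, mid
        if curve[j_match] < match_accuracy:
            lo = mid
        else:
            hi = mid
    return AccuracyCurve(
        tuple(float(a) for a in best_curve),
        n_test,
        float(best_scale),
        float(best_curve[j_match]),
    )
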