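"""General linear model estimation of activation patterns.

Each sequence condition gets one regressor per run: a 13.5 s boxcar at every
trial onset convolved with the canonical double-gamma hemodynamic response,
sampled at the volume grid.  Data and design are high-pass filtered with a
discrete-cosine basis (cut-off 1/128 Hz), and per-voxel coefficients are
estimated by least squares, optionally with robust per-volume reweighting to
down-weight artifact-laden images.  A finite-impulse-response (FIR) variant
estimates the response in 9 TR-wide bins per condition and run, and the main
temporal components of the FIR responses are extracted with an SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH_S = 32.0
HRF_DT_S = 0.05  # internal oversampling grid for convolution

DEFAULT_HIGHPASS_HZ = 1.0 / 128.0
DEFAULT_FIR_BINS = 9
TUKEY_C = 4.685

__all__ = [
    "DesignMatrix",
    "BetaPatterns",
    "TemporalComponents",
    "canonical_hrf",
    "trial_regressor",
    "build_design",
    "build_fir_design",
    "highpass_filter",
    "dct_basis",
    "estimate_betas",
    "estimate_fir",
    "fit_glm",
    "temporal_components",
    "normalize_timecourse",
]


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical hemodynamic response sampled every ``dt`` seconds.

    Sum of two gamma densities (response peaking ~5-6 s, undershoot ~15-16 s,
    undershoot weight 1/6), truncated at 32 s and normalized to unit sum so
    that convolution with a sustained boxcar plateaus at the input amplitude.
    """
    from scipy.stats import gamma

    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_LENGTH_S + dt / 2, dt)
    h = gamma.pdf(t, HRF_PEAK_DELAY_S) - HRF_UNDERSHOOT_RATIO * gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY_S
    )
    return h / h.sum()


def trial_regressor(
    onset: float, duration: float, tr: float, n_volumes: int, dt: float = HRF_DT_S
) -> np.ndarray:
    """One trial's boxcar convolved with the canonical HRF, sampled at TRs."""
    n_fine = int(np.ceil((n_volumes * tr + HRF_LENGTH_S) / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    box = ((t_fine >= onset) & (t_fine < onset + duration)).astype(float)
    conv = np.convolve(box, canonical_hrf(dt))[:n_fine]
    vol_idx = np.rint(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[vol_idx]


@dataclass(frozen=True)
class DesignMatrix:
    """Volumes x regressors matrix with unique labels per column."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[1] != len(self.labels):
            raise ValueError("label count must match regressor count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("regressor labels must be unique")
        if np.any(np.all(m == 0, axis=0)):
            raise ValueError("design contains an all-zero regressor")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class BetaPatterns:
    """Condition x run x voxel activation estimates."""

    betas: np.ndarray  # (n_conditions, n_runs, n_voxels)
    condition_labels: tuple[str, ...] = ()
    run_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 3:
            raise ValueError("betas must be (conditions, runs, voxels)")
        if not np.all(np.isfinite(b)):
            raise ValueError("betas must be finite")
        object.__setattr__(self, "betas", b)
        if not self.condition_labels:
            object.__setattr__(
                self, "condition_labels", tuple(f"seq{i}" for i in range(b.shape[0]))
            )
        if not self.run_labels:
            object.__setattr__(
                self, "run_labels", tuple(f"run{r}" for r in range(b.shape[1]))
            )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.betas, dtype=dtype)


def build_design(schedule, include_rest: bool = False) -> list[DesignMatrix]:
    """One design per run: a convolved-boxcar regressor per condition, plus
    an intercept."""
    designs = []
    for ev in schedule.runs:
        _check_no_overlap(ev)
        cols, labels = [], []
        for cond in range(schedule.n_conditions):
            trials = ev[ev["condition"] == cond]
            if len(trials) == 0:
                continue
            reg = np.zeros(schedule.n_volumes)
            for onset, duration, _ in trials.itertuples(index=False):
                reg += trial_regressor(onset, duration, schedule.tr, schedule.n_volumes)
            cols.append(reg)
            labels.append(f"seq{cond}")
        cols.append(np.ones(schedule.n_volumes))
        labels.append("intercept")
        designs.append(DesignMatrix(np.column_stack(cols), tuple(labels)))
    return designs


def build_fir_design(schedule, n_bins: int = DEFAULT_FIR_BINS) -> list[DesignMatrix]:
    """FIR design: one regressor per condition per post-onset TR bin.

    Bin ``k`` of a trial marks the volumes acquired in the k-th TR after
    trial onset, so the 9 bins tile the first 9 TRs (~24.5 s) of the
    response without assuming a response shape.
    """
    designs = []
    t_vol = np.arange(schedule.n_volumes) * schedule.tr
    for ev in schedule.runs:
        _check_no_overlap(ev)
        cols, labels = [], []
        for cond in range(schedule.n_conditions):
            trials = ev[ev["condition"] == cond]
            if len(trials) == 0:
                continue
            for k in range(n_bins):
                reg = np.zeros(schedule.n_volumes)
                for onset, _, _ in trials.itertuples(index=False):
                    lo = onset + k * schedule.tr
                    hi = onset + (k + 1) * schedule.tr
                    reg += ((t_vol >= lo - 1e-9) & (t_vol < hi - 1e-9)).astype(float)
                cols.append(reg)
                labels.append(f"seq{cond}_bin{k}")
        cols.append(np.ones(schedule.n_volumes))
        labels.append("intercept")
        designs.append(DesignMatrix(np.column_stack(cols), tuple(labels)))
    return designs


def _check_no_overlap(ev) -> None:
    ends = ev["onset"].to_numpy() + ev["duration"].to_numpy()
    if np.any(ev["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
        raise ValueError("overlapping trials")


def dct_basis(n_volumes: int, tr: float, cutoff_hz: float = DEFAULT_HIGHPASS_HZ) -> np.ndarray:
    """Discrete-cosine drift basis: all frequencies below the cut-off,
    including the constant term."""
    n_k = int(np.floor(2.0 * n_volumes * tr * cutoff_hz)) + 1
    n_k = min(n_k, n_volumes)
    n = np.arange(n_volumes)
    basis = np.cos(np.pi * np.outer(n + 0.5, np.arange(n_k)) / n_volumes)
    return basis


def highpass_filter(
    data: np.ndarray, tr: float, cutoff_hz: float = DEFAULT_HIGHPASS_HZ
) -> np.ndarray:
    """Residualize columns of a (volumes x anything) array against the DCT
    drift basis (removes the constant and all slower-than-cutoff drift)."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 8:
        raise ValueError("run too short to filter")
    basis = dct_basis(data.shape[0], tr, cutoff_hz)
    coef, *_ = np.linalg.lstsq(basis, data, rcond=None)
    return data - basis @ coef


def _solve_run(y: np.ndarray, x: np.ndarray, robust: bool) -> np.ndarray:
    """Per-voxel least squares for one run; robust mode reweights volumes."""
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    if not robust:
        return beta
    for _ in range(2):
        resid = y - x @ beta
        msr = np.mean(resid**2, axis=1)
        sd = msr.std()
        u = (msr - msr.mean()) / sd if sd > 0 else np.zeros_like(msr)
        w = np.where(np.abs(u) < TUKEY_C, (1 - (u / TUKEY_C) ** 2) ** 2, 0.0)
        sw = np.sqrt(w)[:, None]
        beta, *_ = np.linalg.lstsq(x * sw, y * sw, rcond=None)
    return beta


def estimate_betas(
    runs: list[np.ndarray], designs: list[DesignMatrix], robust: bool = False
) -> BetaPatterns:
    """Estimate one activation pattern per condition regressor per run."""
    cond_labels = [l for l in designs[0].labels if l != "intercept"]
    per_run = []
    for y, dm in zip(runs, designs):
        beta = _solve_run(np.asarray(y, dtype=float), dm.matrix, robust)
        idx = [dm.labels.index(l) for l in cond_labels]
        per_run.append(beta[idx])
    stacked = np.stack(per_run, axis=1)  # (conditions, runs, voxels)
    return BetaPatterns(stacked, tuple(cond_labels))


def estimate_fir(
    runs: list[np.ndarray],
    designs: list[DesignMatrix],
    n_conditions: int,
    n_bins: int = DEFAULT_FIR_BINS,
    robust: bool = False,
) -> np.ndarray:
    """FIR estimates as a (conditions, runs, bins, voxels) array."""
    bp = estimate_betas(runs, designs, robust=robust)
    b = bp.betas  # (conditions*bins, runs, voxels)
    k_b, n_runs, p = b.shape
    if k_b != n_conditions * n_bins:
        raise ValueError("design labels do not match conditions x bins")
    return b.reshape(n_conditions, n_bins, n_runs, p).transpose(0, 2, 1, 3)


def fit_glm(
    runs: list[np.ndarray],
    schedule,
    robust: bool = False,
    highpass_hz: float | None = DEFAULT_HIGHPASS_HZ,
) -> BetaPatterns:
    """Convenience wrapper: filter data and design identically, then fit."""
    designs = build_design(schedule)
    if highpass_hz is not None:
        runs = [highpass_filter(y, schedule.tr, highpass_hz) for y in runs]
        designs = [
            DesignMatrix(
                np.column_stack(
                    [
                        highpass_filter(dm.matrix[:, :-1], schedule.tr, highpass_hz),
                        np.ones(dm.matrix.shape[0]),
                    ]
                ),
                dm.labels,
            )
            for dm in designs
        ]
    return estimate_betas(runs, designs, robust=robust)


@dataclass(frozen=True)
class TemporalComponents:
    """Main temporal components of the FIR response.

    ``timecourses`` holds one orthonormal 9-bin time course per column,
    ordered by decreasing singular value; ``weights`` holds the projection
    of every (condition-run, voxel) response onto each component.
    """

    timecourses: np.ndarray  # (n_bins, n_components)
    singular_values: np.ndarray  # (n_components,)
    weights: np.ndarray  # (n_components, n_observations, n_voxels)


def temporal_components(fir_betas: np.ndarray, n_components: int = 4) -> TemporalComponents:
    """SVD of FIR responses arranged as bins x (observations * voxels).

    The per-bin mean is removed so components describe the shared response
    shape; the first component captures the dominant activation time course
    and its per-voxel weights are the natural input patterns for
    classification.
    """
    fir = np.asarray(fir_betas, dtype=float)
    k, r, n_bins, p = fir.shape
    if p < 2 or n_bins < 2:
        raise ValueError("need at least 2 voxels and 2 bins")
    x = fir.reshape(k * r, n_bins, p).transpose(1, 0, 2).reshape(n_bins, k * r * p)
    if not np.any(x):
        raise ValueError("all-zero FIR input")
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, len(s))
    w = (s[:n_components, None] * vt[:n_components]).reshape(n_components, k * r, p)
    return TemporalComponents(u[:, :n_components], s[:n_components], w)


def normalize_timecourse(series: np.ndarray) -> np.ndarray:
    """Scale a set of time series by the L2 norm of their mean series."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    norm = np.linalg.norm(series.mean(axis=0))
    if norm == 0:
        raise ValueError("zero-norm average time series")
    return series / norm
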