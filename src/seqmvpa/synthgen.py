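"""Synthetic ground truth, BOLD time series, and behavioral records.

The generative model mirrors the structure the pattern analyses assume: the
activity pattern of condition ``i`` in run ``r`` is

    b_ir = common + specific_i + run_r + noise_ir

where ``common`` is shared by all conditions, ``specific_i`` is unique to a
condition and lives in a controllable low-dimensional subspace with a chosen
geometry, ``run_r`` is shared by all trials of a run, and the trial noise is
independent per observation.  All components are drawn independently per
voxel from zero-mean Gaussians with the requested voxel-wise variances.
BOLD runs place these patterns under boxcar trials convolved with the
canonical hemodynamic response, matching the scanning design of 8 runs of
110 volumes (TR 2.72 s) with 16 trials of 13.5 s and 4 rest phases per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .seqtask import BEHAVIOR_COLUMNS

GEOMETRIES = ("random", "evenly_spaced", "scaled_1d")

# scanning-design defaults
DEFAULT_TR_S = 2.72
DEFAULT_N_VOLUMES = 110
DEFAULT_TRIAL_DURATION_S = 13.5
DEFAULT_N_RUNS = 8
DEFAULT_N_CONDITIONS = 4
DEFAULT_TRIALS_PER_CONDITION = 4
DEFAULT_N_REST = 4

__all__ = [
    "PatternGroundTruth",
    "TrialSchedule",
    "make_ground_truth",
    "simplex_coordinates",
    "make_schedule",
    "simulate_betas",
    "simulate_timeseries",
    "simulate_behavior",
    "write_bold_nifti",
    "write_events_tsv",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class PatternGroundTruth:
    """Generative description of the condition patterns and noise variances."""

    common: np.ndarray  # (n_voxels,)
    specific: np.ndarray  # (n_conditions, n_voxels)
    v_common: float
    v_specific: float
    v_run: float
    v_trial: float
    d: int
    geometry: str

    @property
    def n_voxels(self) -> int:
        return self.common.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.specific.shape[0]


def simplex_coordinates(k: int) -> np.ndarray:
    """Vertices of a centered regular (k-1)-simplex, unit vertex norm.

    Returns a (k, k-1) matrix whose rows sum to zero, have equal norms and
    equal pairwise distances.
    """
    eye = np.eye(k)
    centered = eye - eye.mean(axis=0)
    # rows of `centered` already form a regular simplex in a (k-1)-dim subspace
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, : k - 1] * s[: k - 1]
    return coords / np.linalg.norm(coords, axis=1, keepdims=True)


def make_ground_truth(
    n_voxels: int,
    v_common: float,
    v_specific: float,
    v_run: float,
    v_trial: float,
    d: int = 3,
    geometry: str = "random",
    n_conditions: int = DEFAULT_N_CONDITIONS,
    rng_seed: int | None = None,
) -> PatternGroundTruth:
    """Draw common and condition-specific patterns with the requested structure.

    The specific patterns are linear combinations of ``d`` independent
    Gaussian voxel maps; the coordinate geometry controls how conditions are
    arranged in that subspace:

    - ``random``: coordinates drawn independently, N(0, v_specific/d)
    - ``evenly_spaced``: a regular simplex (all pairwise distances equal),
      requires d == n_conditions - 1
    - ``scaled_1d``: all conditions are scalar multiples of one voxel map,
      requires d == 1

    Each specific pattern has (expected) voxel-wise variance ``v_specific``.
    """
    if min(v_common, v_specific, v_run, v_trial) < 0:
        raise ValueError("variances must be non-negative")
    if n_voxels < n_conditions:
        raise ValueError("need at least as many voxels as conditions")
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}")
    if not 1 <= d <= n_conditions - 1:
        raise ValueError(f"d must be in 1..{n_conditions - 1}")
    if geometry == "evenly_spaced" and d != n_conditions - 1:
        raise ValueError(
            f"evenly_spaced with {n_conditions} conditions requires d={n_conditions - 1}"
        )
    if geometry == "scaled_1d" and d != 1:
        raise ValueError("scaled_1d requires d=1")

    rng = np.random.default_rng(rng_seed)
    common = rng.normal(0.0, np.sqrt(v_common), size=n_voxels)
    if geometry == "evenly_spaced":
        # orthonormal basis (scaled to unit voxel variance) keeps the
        # simplex exact: all pairwise pattern distances strictly equal
        q, _ = np.linalg.qr(rng.normal(size=(n_voxels, d)))
        basis = q.T * np.sqrt(n_voxels)
        coords = simplex_coordinates(n_conditions) * np.sqrt(v_specific)
    elif geometry == "scaled_1d":
        basis = rng.normal(0.0, 1.0, size=(d, n_voxels))
        coords = rng.normal(0.0, np.sqrt(v_specific), size=(n_conditions, 1))
    else:
        basis = rng.normal(0.0, 1.0, size=(d, n_voxels))
        coords = rng.normal(0.0, np.sqrt(v_specific / d), size=(n_conditions, d))
    specific = coords @ basis
    return PatternGroundTruth(
        common=common,
        specific=specific,
        v_common=float(v_common),
        v_specific=float(v_specific),
        v_run=float(v_run),
        v_trial=float(v_trial),
        d=int(d),
        geometry=geometry,
    )


@dataclass(frozen=True)
class TrialSchedule:
    """Per-run trial timing: onsets, durations and condition labels.

    ``runs`` holds one events table per run with columns
    (onset, duration, condition); rest phases carry condition -1.
    """

    runs: tuple[pd.DataFrame, ...]
    n_volumes: int
    tr: float
    n_conditions: int

    def __post_init__(self) -> None:
        for ev in self.runs:
            ends = ev["onset"].to_numpy() + ev["duration"].to_numpy()
            if np.any(ev["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
                raise ValueError("overlapping trials in schedule")
            if ends.max() > self.n_volumes * self.tr + 1e-9:
                raise ValueError("schedule extends past the end of the run")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def make_schedule(
    n_runs: int = DEFAULT_N_RUNS,
    n_conditions: int = DEFAULT_N_CONDITIONS,
    trials_per_condition: int = DEFAULT_TRIALS_PER_CONDITION,
    n_rest: int = DEFAULT_N_REST,
    trial_duration: float = DEFAULT_TRIAL_DURATION_S,
    n_volumes: int = DEFAULT_N_VOLUMES,
    tr: float = DEFAULT_TR_S,
    rng_seed: int | None = None,
) -> TrialSchedule:
    """Randomly ordered trials on a fixed 13.5 s grid, rests interspersed."""
    rng = np.random.default_rng(rng_seed)
    runs = []
    for _ in range(n_runs):
        slots = np.repeat(np.arange(n_conditions), trials_per_condition)
        slots = np.concatenate([slots, np.full(n_rest, -1)])
        rng.shuffle(slots)
        onsets = np.arange(len(slots)) * trial_duration
        ev = pd.DataFrame(
            {
                "onset": onsets,
                "duration": np.full(len(slots), trial_duration),
                "condition": slots.astype(int),
            }
        )
        runs.append(ev)
    return TrialSchedule(tuple(runs), int(n_volumes), float(tr), int(n_conditions))


def simulate_betas(
    gt: PatternGroundTruth, n_runs: int = DEFAULT_N_RUNS, rng_seed: int | None = None
) -> np.ndarray:
    """Draw run-wise activation patterns directly at the pattern level.

    Returns a (n_conditions, n_runs, n_voxels) array:
    common + specific + run effect + independent trial noise.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    rng = np.random.default_rng(rng_seed)
    k, p = gt.specific.shape
    run_eff = rng.normal(0.0, np.sqrt(gt.v_run), size=(n_runs, p))
    noise = rng.normal(0.0, np.sqrt(gt.v_trial), size=(k, n_runs, p))
    return gt.common[None, None, :] + gt.specific[:, None, :] + run_eff[None, :, :] + noise


def simulate_timeseries(
    gt: PatternGroundTruth,
    schedule: TrialSchedule,
    noise_sd: float = 1.0,
    rng_seed: int | None = None,
    drift_amplitude: float = 0.0,
) -> list[np.ndarray]:
    """Generate BOLD runs from the ground truth under a trial schedule.

    Every trial contributes its condition's pattern (common + specific +
    run effect + a fresh trial-noise draw) multiplied by its boxcar
    convolved with the canonical HRF; Gaussian scanner noise with standard
    deviation ``noise_sd`` is added per volume and voxel, plus an optional
    low-frequency cosine drift.
    """
    from .glm import trial_regressor  # deferred: avoids import cycle

    rng = np.random.default_rng(rng_seed)
    p = gt.n_voxels
    t_vol = np.arange(schedule.n_volumes) * schedule.tr
    out = []
    for ev in schedule.runs:
        run_eff = rng.normal(0.0, np.sqrt(gt.v_run), size=p)
        y = np.zeros((schedule.n_volumes, p))
        for onset, duration, cond in ev.itertuples(index=False):
            if cond < 0:
                continue
            pattern = (
                gt.common
                + gt.specific[cond]
                + run_eff
                + rng.normal(0.0, np.sqrt(gt.v_trial), size=p)
            )
            reg = trial_regressor(onset, duration, schedule.tr, schedule.n_volumes)
            y += np.outer(reg, pattern)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd, size=y.shape)
        if drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            y += drift_amplitude * np.cos(
                2 * np.pi * t_vol / (t_vol[-1] * 2) + phase
            )[:, None]
        out.append(y)
    return out


def simulate_behavior(
    schedule: TrialSchedule,
    mt_means_ms: dict[int, float] | list[float],
    mt_sd_ms: float = 150.0,
    error_rate: float = 0.12,
    force_mean_n: float = 4.2,
    force_sd_n: float = 0.6,
    subject: int = 0,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Per-trial movement times, peak forces and error flags.

    Defaults emulate in-scanner performance: MT spread ~150 ms within a
    condition, ~12% error trials, ~4.2 N mean peak force per finger.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    if isinstance(mt_means_ms, dict):
        means = mt_means_ms
    else:
        means = dict(enumerate(mt_means_ms))
    rng = np.random.default_rng(rng_seed)
    rows = []
    for run_idx, ev in enumerate(schedule.runs):
        trial_idx = 0
        for _, _, cond in ev.itertuples(index=False):
            if cond < 0:
                continue
            mt = max(1.0, rng.normal(means[cond], mt_sd_ms))
            forces = np.maximum(0.0, rng.normal(force_mean_n, force_sd_n, size=5))
            rows.append(
                {
                    "subject": subject,
                    "run": run_idx,
                    "trial": trial_idx,
                    "sequence": cond,
                    "condition": cond,
                    "MT_ms": mt,
                    **{f"force_f{i + 1}": forces[i] for i in range(5)},
                    "error": bool(rng.uniform() < error_rate),
                }
            )
            trial_idx += 1
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


# -- external formats --------------------------------------------------------


def write_bold_nifti(run: np.ndarray, grid_shape: tuple[int, ...], tr: float, path) -> None:
    """Write one BOLD run (volumes x voxels) as a 4-D NIfTI volume."""
    import nibabel as nib

    t, p = run.shape
    shape3 = tuple(grid_shape) + (1,) * (3 - len(grid_shape))
    if int(np.prod(shape3)) != p:
        raise ValueError("grid shape does not match voxel count")
    img_data = run.T.reshape(shape3 + (t,))
    img = nib.Nifti1Image(np.asarray(img_data, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write one run's schedule as a BIDS-style events table."""
    out = events[events["condition"] >= 0].copy()
    out["trial_type"] = out["condition"].map(lambda c: f"seq{c}")
    out[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def save_ground_truth(gt: PatternGroundTruth, path) -> None:
    doc = {
        "v_common": gt.v_common,
        "v_specific": gt.v_specific,
        "v_run": gt.v_run,
        "v_trial": gt.v_trial,
        "d": gt.d,
        "geometry": gt.geometry,
        "common": gt.common.tolist(),
        "specific": gt.specific.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_ground_truth(path) -> PatternGroundTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PatternGroundTruth(
        common=np.asarray(doc["common"], dtype=float),
        specific=np.asarray(doc["specific"], dtype=float),
        v_common=doc["v_common"],
        v_specific=doc["v_specific"],
        v_run=doc["v_run"],
        v_trial=doc["v_trial"],
        d=doc["d"],
        geometry=doc["geometry"],
    )
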