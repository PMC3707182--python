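"""Pattern-component variance decomposition.

Splits run-wise activation patterns into four additive voxel-wise variance
components: a pattern common to all conditions, a condition-specific
pattern, a run-common effect, and independent trial noise.  The estimator
is a method of moments on raw voxel cross-products: writing
m(i,r; j,r') for the mean over voxels of b_ir * b_jr', the four averages

    different condition, different run  ->  v_common
    same condition,      different run  ->  v_common + v_specific
    different condition, same run       ->  v_common + v_run
    same condition,      same run       ->  v_common + v_specific + v_run + v_trial

identify the components linearly.  Raw cross-products are used on purpose:
removing the mean pattern would absorb the common component, which is
itself a quantity of interest.  Classification accuracy tracks the ratio of
the specific component to the trial-noise component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["VarianceComponents", "decompose", "specific_to_noise_ratio"]


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated voxel-by-voxel variances (clipped at zero) plus raw values."""

    v_common: float
    v_specific: float
    v_run: float
    v_trial: float
    raw: tuple[float, float, float, float]

    @property
    def common_to_noise(self) -> float:
        if self.v_trial <= 0:
            raise ValueError("noise variance is zero")
        return self.v_common / self.v_trial

    @property
    def specific_to_noise(self) -> float:
        if self.v_trial <= 0:
            raise ValueError("noise variance is zero")
        return self.v_specific / self.v_trial

    @property
    def common_share(self) -> float:
        """Fraction of pattern (common + specific) variance that is common."""
        tot = self.v_common + self.v_specific
        return self.v_common / tot if tot > 0 else np.nan


def decompose(betas: np.ndarray) -> VarianceComponents:
    """Method-of-moments estimate of the four pattern-component variances.

    ``betas`` is (conditions, runs, voxels) with at least 2 conditions and
    2 runs.  Negative solutions (possible at low signal-to-noise) are
    clipped to zero with a warning; the unclipped values are kept in
    ``raw``.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim != 3:
        raise ValueError("betas must be (conditions, runs, voxels)")
    k, r, p = b.shape
    if k < 2 or r < 2:
        raise ValueError("need at least 2 conditions and 2 runs")

    flat = b.reshape(k * r, p)
    g = flat @ flat.T / p  # mean voxel cross-products, (k*r, k*r)
    cond = np.repeat(np.arange(k), r)
    run = np.tile(np.arange(r), k)
    same_cond = cond[:, None] == cond[None, :]
    same_run = run[:, None] == run[None, :]

    m_dd = g[~same_cond & ~same_run].mean()
    m_sd = g[same_cond & ~same_run].mean()
    m_ds = g[~same_cond & same_run].mean()
    m_ss = g[same_cond & same_run].mean()

    raw = (
        float(m_dd),
        float(m_sd - m_dd),
        float(m_ds - m_dd),
        float(m_ss - m_sd - m_ds + m_dd),
    )
    if min(raw) < 0:
        warnings.warn(
            f"negative variance estimate(s) clipped to zero (raw: {raw})",
            stacklevel=2,
        )
    clipped = tuple(max(0.0, v) for v in raw)
    return VarianceComponents(*clipped, raw=raw)


def specific_to_noise_ratio(vc: VarianceComponents) -> tuple[float, float]:
    """(specific/noise, common/noise) variance ratios."""
    return vc.specific_to_noise, vc.common_to_noise
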