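"""Comparison metrics for simulation studies and residual diagnostics.

Implements the agreement and error summaries used to compare optimizers:
flattened source correlation, total MSE split by true active/inactive region
and decomposed exactly into total squared bias plus total variance (1/R
normalization, so the identity is exact), relative percentage improvement,
sampling metrics for the estimated number of components, per-location total
power, and plot-ready residual diagnostic tables.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import FitResult, InputError
from .simulate import GroundTruth


class ZeroVarianceError(ValueError):
    """Correlation is undefined when one argument has zero variance."""


@dataclasses.dataclass
class ReplicateSet:
    """Paired (fit, truth) results from R replicate simulations.

    Replicates must share dimensions, K_true and the active-region mask so
    that region-wise error totals are well defined.
    """

    pairs: List[Tuple[FitResult, GroundTruth]]
    seeds: Optional[Sequence[int]] = None

    def __post_init__(self):
        if not self.pairs:
            raise InputError("ReplicateSet must be non-empty")
        f0, t0 = self.pairs[0]
        for f, t in self.pairs:
            if f.sources.S.shape != f0.sources.S.shape:
                raise InputError("replicates disagree on source dimensions")
            if t.K_true != t0.K_true:
                raise InputError("replicates disagree on K_true")
            if not np.array_equal(t.active_mask, t0.active_mask):
                raise InputError("replicates disagree on the active-region mask")

    @property
    def R(self) -> int:
        return len(self.pairs)


def source_correlation(S_true: np.ndarray, S_hat: np.ndarray) -> float:
    """Pearson correlation of the two source fields flattened over (location, time)."""
    a = np.asarray(S_true, dtype=float).ravel()
    b = np.asarray(S_hat, dtype=float).ravel()
    if a.shape != b.shape:
        raise InputError("source fields must have the same shape")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ZeroVarianceError("correlation undefined: an argument has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


@dataclasses.dataclass
class RegionTmse:
    tmse: float
    total_bias2: float
    total_var: float


def tmse_report(reps: ReplicateSet) -> Dict[str, RegionTmse]:
    """Total MSE by region with its exact bias^2 + variance decomposition.

    Per (location, time): MSE = mean_r (error_r)^2, bias = mean_r error_r,
    var = mean_r (error_r - bias)^2 with errors ``S_hat_r - S_true_r``;
    totals sum over the (j, t) cells of each region.  With the 1/R convention
    TMSE = total_bias^2 + total_var holds exactly.
    """
    if reps.R < 2:
        raise InputError("at least 2 replicates are required")
    errors = np.stack([f.sources.S - t.S_true for f, t in reps.pairs])  # R x P x T
    mse = np.mean(errors**2, axis=0)
    bias = np.mean(errors, axis=0)
    var = np.mean((errors - bias[None]) ** 2, axis=0)
    mask = reps.pairs[0][1].active_mask
    out = {}
    for name, sel in (("active", mask), ("inactive", ~mask)):
        out[name] = RegionTmse(
            tmse=float(np.sum(mse[sel])),
            total_bias2=float(np.sum(bias[sel] ** 2)),
            total_var=float(np.sum(var[sel])),
        )
    return out


def relative_improvement(tmse_ref: float, tmse_new: float) -> float:
    """Percent improvement 100 * (ref - new) / ref of the new method over the reference."""
    if tmse_ref <= 0:
        raise InputError("reference TMSE must be positive")
    return 100.0 * (tmse_ref - tmse_new) / tmse_ref


def khat_metrics(khats: Sequence[int], K_true: int) -> Tuple[float, float, Dict[int, int]]:
    """Bias, MSE and histogram of the estimated number of mixture components."""
    k = np.asarray(list(khats), dtype=float)
    if k.size == 0:
        raise InputError("khats must be non-empty")
    bias = float(np.mean(k) - K_true)
    mse = float(np.mean((k - K_true) ** 2))
    values, counts = np.unique(k.astype(int), return_counts=True)
    return bias, mse, dict(zip(values.tolist(), counts.tolist()))


def total_power(sources) -> np.ndarray:
    """Per-location power sum_t S_j(t)^2 (accepts a SourceField or a P x T array)."""
    S = sources.S if hasattr(sources, "S") else np.asarray(sources)
    return np.sum(S**2, axis=1)


def residual_summary(eps: np.ndarray, fitted: Optional[np.ndarray] = None) -> Dict[str, object]:
    """Plot-ready residual diagnostics for one modality.

    Returns per-sensor mean/variance, the pooled standardized QQ table
    (ordered residuals against standard-normal quantiles), optional
    residual-vs-fitted pairs, and the indices of zero-variance sensors.
    """
    eps = np.asarray(eps, dtype=float)
    per_sensor = pd.DataFrame(
        {"mean": eps.mean(axis=1), "variance": eps.var(axis=1)},
        index=pd.RangeIndex(eps.shape[0], name="sensor"),
    )
    zero_var = np.flatnonzero(per_sensor["variance"].to_numpy() == 0.0)

    pooled = eps.ravel()
    sd = pooled.std()
    std = (pooled - pooled.mean()) / sd if sd > 0 else np.zeros_like(pooled)
    n = std.size
    qq = pd.DataFrame(
        {
            "theoretical": stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n),
            "sample": np.sort(std),
        }
    )
    out: Dict[str, object] = {
        "per_sensor": per_sensor,
        "qq": qq,
        "zero_variance_sensors": zero_var,
    }
    if fitted is not None:
        fitted = np.asarray(fitted, dtype=float)
        if fitted.shape != eps.shape:
            raise InputError("fitted values must match the residual shape")
        out["residual_vs_fitted"] = pd.DataFrame(
            {"fitted": fitted.ravel(), "residual": eps.ravel()}
        )
    return out
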