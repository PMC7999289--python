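"""Nonparametric trial-resampling bootstrap around the point estimates.

Trials are resampled with replacement independently per modality (the two
recordings come from separate sessions with different trial counts), averaged
into an evoked-response dataset, and refit; the spread of the replicate fits
yields standard errors of total power (hence T-maps) and pointwise percentile
confidence intervals for source time courses.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import List, Optional

import numpy as np

from .acs import AcsTuning, acs_icm_run
from .icm import IcmSettings, icm_run
from .initialize import default_init
from .model import FitResult, Hyperparameters, InputError, SensorDataset
from .spatial import ClusterMap, VoxelGrid

logger = logging.getLogger(__name__)


@dataclasses.dataclass(eq=False)
class TrialData:
    """Trial-level two-modality recordings plus forward operators."""

    meg_trials: np.ndarray  # n_trials_M x n_M x T
    eeg_trials: np.ndarray  # n_trials_E x n_E x T
    X_M: np.ndarray
    X_E: np.ndarray
    H_M: Optional[np.ndarray] = None
    H_E: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None

    def __post_init__(self):
        self.meg_trials = np.asarray(self.meg_trials, dtype=np.float64)
        self.eeg_trials = np.asarray(self.eeg_trials, dtype=np.float64)
        for name, t in (("meg_trials", self.meg_trials), ("eeg_trials", self.eeg_trials)):
            if t.ndim != 3 or t.shape[0] < 1:
                raise InputError(f"{name} must be (n_trials, sensors, T) with at least one trial")
        if self.meg_trials.shape[2] != self.eeg_trials.shape[2]:
            raise InputError("modalities disagree on the number of time points")
        if self.meg_trials.shape[1] != np.asarray(self.X_M).shape[0]:
            raise InputError("meg_trials and X_M disagree on the number of MEG sensors")
        if self.eeg_trials.shape[1] != np.asarray(self.X_E).shape[0]:
            raise InputError("eeg_trials and X_E disagree on the number of EEG sensors")

    @property
    def n_trials_M(self) -> int:
        return self.meg_trials.shape[0]

    @property
    def n_trials_E(self) -> int:
        return self.eeg_trials.shape[0]


@dataclasses.dataclass
class FitConfig:
    """How each bootstrap replicate is fit."""

    hyper: Hyperparameters
    grid: VoxelGrid
    clusters: Optional[ClusterMap] = None
    icm_settings: Optional[IcmSettings] = None
    tuning: Optional[AcsTuning] = None
    algorithm: str = "acs"  # "acs" or "icm"

    def __post_init__(self):
        if self.algorithm not in ("acs", "icm"):
            raise InputError("algorithm must be 'acs' or 'icm'")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if hasattr(seed_or_rng, "integers"):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def resample_average(trials: TrialData, seed=0) -> SensorDataset:
    """One bootstrap resample: draw trials with replacement per modality, average.

    ``seed`` may be an integer or any generator-like object exposing
    ``integers`` (so tests can force particular index draws).
    """
    rng = _as_rng(seed)
    im = np.asarray(rng.integers(0, trials.n_trials_M, size=trials.n_trials_M))
    ie = np.asarray(rng.integers(0, trials.n_trials_E, size=trials.n_trials_E))
    M = trials.meg_trials[im].mean(axis=0)
    E = trials.eeg_trials[ie].mean(axis=0)
    return SensorDataset(
        M=M, E=E, X_M=trials.X_M, X_E=trials.X_E,
        H_M=trials.H_M, H_E=trials.H_E, coords=trials.coords,
    )


def bootstrap_fit(trials: TrialData, B: int, fit_config: FitConfig, seed: int = 0) -> List[FitResult]:
    """B independent resample -> refit pipelines with per-replicate seed substreams.

    Each replicate draws its randomness from a deterministic child of the
    master seed indexed by the replicate number, so results do not depend on
    execution order.  Failed replicates are logged and dropped.
    """
    if B < 2:
        raise InputError("B must be at least 2")
    # fit seeds derive from the master seed only: identical resampled data
    # must produce identical fits, whatever the replicate index
    fit_seeds = np.random.SeedSequence(seed).generate_state(2)
    results: List[FitResult] = []
    for b in range(B):
        ss = np.random.SeedSequence(seed, spawn_key=(b,))
        try:
            dataset = resample_average(trials, np.random.default_rng(ss))
            init = default_init(dataset, fit_config.grid, fit_config.hyper,
                                seed=int(fit_seeds[0] % (2**31)))
            if fit_config.algorithm == "acs":
                tuning = dataclasses.replace(
                    fit_config.tuning or AcsTuning(), seed=int(fit_seeds[1] % (2**31))
                )
                fit = acs_icm_run(dataset, init, fit_config.hyper, fit_config.grid,
                                  fit_config.clusters, tuning, fit_config.icm_settings)
            else:
                fit = icm_run(dataset, init, fit_config.hyper, fit_config.grid,
                              fit_config.clusters, fit_config.icm_settings)
        except RuntimeError as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        results.append(fit)
    logger.info("bootstrap: %d of %d replicates completed", len(results), B)
    return results


def tmap(point_power: np.ndarray, boot_powers: np.ndarray) -> np.ndarray:
    """Per-location ratio of point-estimate power to its bootstrap SD.

    Locations where the bootstrap SD is zero are returned as NaN (undefined),
    never infinity.  The map is invariant to a common positive rescaling of
    all source estimates.
    """
    point_power = np.asarray(point_power, dtype=float)
    boot_powers = np.asarray(boot_powers, dtype=float)
    if boot_powers.ndim != 2 or boot_powers.shape[0] < 2:
        raise InputError("boot_powers must be B x P with B >= 2")
    if boot_powers.shape[1] != point_power.shape[0]:
        raise InputError("boot_powers and point_power disagree on P")
    sd = boot_powers.std(axis=0, ddof=1)
    out = np.full(point_power.shape, np.nan)
    ok = sd > 0
    out[ok] = point_power[ok] / sd[ok]
    return out


def ci_timecourse(
    boot_sources: np.ndarray,
    location: int,
    level: float = 0.95,
):
    """Pointwise percentile confidence band for one location's time course.

    Returns ``(lower, upper)`` T-vectors at the (1 -/+ level)/2 quantiles of
    the B replicate estimates.  Warns when B is too small to resolve the
    requested tail quantiles.
    """
    boot_sources = np.asarray(boot_sources, dtype=float)
    if boot_sources.ndim != 3:
        raise InputError("boot_sources must be B x P x T")
    if not (0.0 < level < 1.0):
        raise InputError("level must be in (0, 1)")
    B = boot_sources.shape[0]
    if B < 2.0 / (1.0 - level):
        warnings.warn(
            f"B={B} replicates are few for a {level:.0%} percentile interval",
            stacklevel=2,
        )
    draws = boot_sources[:, location, :]
    lower = np.quantile(draws, (1.0 - level) / 2.0, axis=0)
    upper = np.quantile(draws, (1.0 + level) / 2.0, axis=0)
    return lower, upper
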