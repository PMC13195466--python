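"""Model-performance statistics, cross-validation and benchmark checks.

Statistics follow the conventions of regulatory air-quality model
evaluation: mean bias (MB), root-mean-square error (RMSE), normalized mean
bias/error (NMB/NME, normalized by the summed observations) and mean
normalized bias/error (MNB/MNE, normalized pair by pair, restricted to
observations above a floor to avoid division blow-up), plus the squared
Pearson correlation.

Cross-validation withholds whole monitor *sites*, not individual records:
the fusion interpolates spatially, so holding out single observations from
a site that stays in the training set would leak information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, DegenerateInputError, InputError
from .fields import TOTAL
from .fusion import FusionConfig, exclude_near_road, fuse_total, _collocate
from .grid import GridDefinition

__all__ = [
    "PerformanceStats",
    "compute_stats",
    "kfold_cv",
    "CrossValidationResult",
    "benchmark_flags",
    "EMERY_GOALS",
    "EMERY_CRITERIA",
    "count_impact_exceeding_observation",
]

#: Photochemical-model performance *goals* for 24 h PM2.5 (the stricter tier).
EMERY_GOALS: dict[str, float] = {"abs_nmb_max_pct": 10.0, "nme_max_pct": 35.0}

#: Photochemical-model performance *criteria* for 24 h PM2.5 (the looser tier).
EMERY_CRITERIA: dict[str, float] = {"abs_nmb_max_pct": 30.0, "nme_max_pct": 50.0}


@dataclass(frozen=True)
class PerformanceStats:
    """Paired model/observation summary statistics.

    Concentrations in ug/m3; NMB/NME/MNB/MNE in percent.
    """

    n: int
    mb: float
    rmse: float
    nmb: float
    nme: float
    mnb: float
    mne: float
    r_squared: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "MB": self.mb,
            "RMSE": self.rmse,
            "NMB": self.nmb,
            "NME": self.nme,
            "MNB": self.mnb,
            "MNE": self.mne,
            "R2": self.r_squared,
        }


def compute_stats(
    model: np.ndarray,
    observed: np.ndarray,
    mnb_obs_floor: float = 1.0,
) -> PerformanceStats:
    """Performance statistics over paired model/observed values.

    ``MNB``/``MNE`` average per-pair normalized deviations over pairs whose
    observation is at least ``mnb_obs_floor`` (ug/m3); the other statistics
    use every pair.
    """
    m = np.asarray(model, dtype=float)
    o = np.asarray(observed, dtype=float)
    if m.shape != o.shape:
        raise InputError("model and observed arrays differ in length")
    if m.size < 2:
        raise InputError("at least two pairs are required")
    if (o < 0).any():
        raise InputError("observed values must be nonnegative")
    if o.sum() <= 0:
        raise DegenerateInputError("observations sum to zero; normalized stats undefined")

    diff = m - o
    mb = float(diff.mean())
    rmse = float(np.sqrt(np.mean(diff**2)))
    nmb = float(100.0 * diff.sum() / o.sum())
    nme = float(100.0 * np.abs(diff).sum() / o.sum())

    ok = o >= mnb_obs_floor
    if ok.any():
        mnb = float(100.0 * np.mean(diff[ok] / o[ok]))
        mne = float(100.0 * np.mean(np.abs(diff[ok]) / o[ok]))
    else:
        mnb = mne = float("nan")

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(m, o)[0, 1]
    r2 = float(corr**2) if np.isfinite(corr) else float("nan")
    return PerformanceStats(n=int(m.size), mb=mb, rmse=rmse, nmb=nmb, nme=nme,
                            mnb=mnb, mne=mne, r_squared=r2)


def benchmark_flags(stats: PerformanceStats, thresholds: dict[str, float]) -> dict[str, bool]:
    """Pass/fail flags against configured benchmark thresholds.

    Recognized keys: ``abs_nmb_max_pct`` (|NMB| at or below the value) and
    ``nme_max_pct`` (NME at or below the value).
    """
    flags: dict[str, bool] = {}
    for key, value in thresholds.items():
        if key == "abs_nmb_max_pct":
            flags[key] = abs(stats.nmb) <= value
        elif key == "nme_max_pct":
            flags[key] = stats.nme <= value
        else:
            raise ConfigurationError(f"unknown benchmark criterion {key!r}")
    return flags


# ---------------------------------------------------------------------------
# cross-validation of the fusion
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationResult:
    """Per-fold and pooled statistics for model-vs-obs and fused-vs-obs."""

    folds: list[dict[str, PerformanceStats]]
    pooled_sim: PerformanceStats
    pooled_fused: PerformanceStats
    fold_assignment: dict[str, int]


def partition_sites(site_ids: list[str], k: int, seed: int) -> dict[str, int]:
    """Deterministic random partition of sites into k disjoint folds."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(site_ids) < k:
        raise ConfigurationError("need at least k sites for k folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(site_ids))
    return {sid: i % k for i, sid in enumerate(order)}


def kfold_cv(
    sim_total: xr.DataArray,
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    grid: GridDefinition,
    k: int = 10,
    seed: int = 0,
    config: FusionConfig = FusionConfig(),
) -> CrossValidationResult:
    """k-fold site-held-out cross-validation of total-PM2.5 fusion.

    Near-road sites are excluded up front.  Sites with total-PM2.5
    observations are partitioned into k folds; for each fold the fusion is
    refit with the fold's observations withheld and evaluated against the
    withheld observations at the withheld sites' cells.  Every observation
    lands in exactly one test fold.
    """
    obs = exclude_near_road(observations, sites)
    obs_tot = obs[obs["species"] == TOTAL]
    usable_sites = sorted(set(obs_tot["site"]))
    assignment = partition_sites(usable_sites, k, seed)

    folds: list[dict[str, PerformanceStats]] = []
    all_sim: list[np.ndarray] = []
    all_fused: list[np.ndarray] = []
    all_obs: list[np.ndarray] = []
    for fold in range(k):
        test_sites = {s for s, f in assignment.items() if f == fold}
        train = obs_tot[~obs_tot["site"].isin(test_sites)]
        test = obs_tot[obs_tot["site"].isin(test_sites)]
        fused = fuse_total(sim_total, train, sites, grid, config)
        held = _collocate(test, sites, sim_total, TOTAL)
        fused_at = fused.values[
            held["day"].to_numpy(), held["row"].to_numpy(int), held["col"].to_numpy(int)
        ]
        o = held["value"].to_numpy()
        s = held["sim"].to_numpy()
        folds.append(
            {
                "sim": compute_stats(s, o),
                "fused": compute_stats(fused_at, o),
            }
        )
        all_sim.append(s)
        all_fused.append(fused_at)
        all_obs.append(o)

    pooled_sim = compute_stats(np.concatenate(all_sim), np.concatenate(all_obs))
    pooled_fused = compute_stats(np.concatenate(all_fused), np.concatenate(all_obs))
    return CrossValidationResult(
        folds=folds,
        pooled_sim=pooled_sim,
        pooled_fused=pooled_fused,
        fold_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# physical-consistency diagnostic
# ---------------------------------------------------------------------------


def count_impact_exceeding_observation(
    delta: xr.DataArray,
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    species: str,
) -> int:
    """Count collocated monitor-days where the estimated source impact
    exceeds the observed concentration of the same species.

    A source's contribution cannot physically exceed the total observed
    amount, so each such cell-day flags a model (or fusion) artifact; a
    good fusion should shrink this count.
    """
    coll = _collocate(observations, sites, delta, species)
    delta_at = delta.values[
        coll["day"].to_numpy(), coll["row"].to_numpy(int), coll["col"].to_numpy(int)
    ]
    return int((delta_at > coll["value"].to_numpy()).sum())
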