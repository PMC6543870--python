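"""Relative residence times from replica-structured egress-time samples.

The tauRAMD statistic for one equilibration replica is the time by which
half of its dissociation trajectories have shown an egress event — the
interpolated median of the egress times, with censored (non-dissociating)
trajectories counted as longer than every observed time. The compound-level
estimate averages the replica medians; the replica-to-replica standard
deviation is the uncertainty. Relative values are mapped onto the
experimental residence-time scale by an ordinary least-squares fit of
log10(tauRAMD) against log10(1/k_off), optionally excluding flagged
outlier compounds. All model quantities are on the log10 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EgressTimes",
    "InsufficientSamplingError",
    "Replica",
    "ResidenceEstimate",
    "ScalingFit",
    "TauEvaluation",
    "clamp_out_of_range",
    "evaluate_tau",
    "fit_scaling",
    "replica_t50",
    "tau_ramd",
]


class InsufficientSamplingError(ValueError):
    """Raised when too few trajectories dissociated to define the statistic."""


@dataclass
class Replica:
    replica_id: str
    times: np.ndarray               # egress times, ns
    censored: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, bool)
        self.censored = np.asarray(self.censored, bool)
        if self.times.size == 0:
            raise ValueError("replica has no trajectories")
        if (self.times[~self.censored] <= 0).any():
            raise ValueError("egress times must be positive")


@dataclass
class EgressTimes:
    """Egress times of all dissociation trajectories of one compound, per replica."""

    compound_id: str
    replicas: list

    def __post_init__(self):
        if not self.replicas:
            raise ValueError("at least one replica is required")

    @classmethod
    def from_csv(cls, path):
        """Read an egress-time table (compound, replica, trajectory, time_ns,
        censored) and return a list of EgressTimes, one per compound."""
        table = pd.read_csv(path)
        out = []
        for cid, group in table.groupby("compound", sort=True):
            reps = [Replica(str(rid),
                            sub["time_ns"].to_numpy(float),
                            sub.get("censored",
                                    pd.Series(False, index=sub.index))
                            .astype(bool).to_numpy())
                    for rid, sub in group.groupby("replica", sort=True)]
            out.append(cls(str(cid), reps))
        return out

    def to_records(self):
        for rep in self.replicas:
            for k, (t, c) in enumerate(zip(rep.times, rep.censored)):
                yield {"compound": self.compound_id, "replica": rep.replica_id,
                       "trajectory": k, "time_ns": float(t),
                       "censored": bool(c)}


@dataclass
class ResidenceEstimate:
    """Relative residence time of one compound with replica-level uncertainty."""

    compound_id: str
    tau_ramd: float                 # ns, mean of replica medians
    replica_sd: float               # ns, SD across replicas (0 for one replica)
    n_replicas: int
    scaled_log_tau: float | None = None   # log10(s), after scaling fit

    def __post_init__(self):
        if self.tau_ramd <= 0 or self.replica_sd < 0:
            raise ValueError("tau_ramd must be > 0 and replica_sd >= 0")


def replica_t50(times, censored=None) -> float:
    """Time by which 50 % of a replica's trajectories have dissociated.

    Interpolated median of the egress times; censored entries count as
    longer than every observed time. Fails when half or more of the
    trajectories are censored.
    """
    times = np.asarray(times, float)
    if censored is None:
        censored = np.zeros(times.shape, bool)
    censored = np.asarray(censored, bool)
    n = times.size
    if n == 0 or (~censored).sum() == 0:
        raise InsufficientSamplingError("no uncensored egress times")
    if censored.sum() * 2 >= n:
        raise InsufficientSamplingError(
            f"{censored.sum()}/{n} trajectories censored; simulate more "
            "trajectories or replicas")
    obs = np.sort(times[~censored])
    if n % 2 == 1:
        return float(obs[(n - 1) // 2])
    return float(0.5 * (obs[n // 2 - 1] + obs[n // 2]))


def tau_ramd(egress: EgressTimes) -> ResidenceEstimate:
    """Compound-level relative residence time: mean of replica medians."""
    t50s = np.array([replica_t50(r.times, r.censored)
                     for r in egress.replicas])
    sd = float(t50s.std(ddof=1)) if t50s.size > 1 else 0.0
    return ResidenceEstimate(
        compound_id=egress.compound_id,
        tau_ramd=float(t50s.mean()),
        replica_sd=sd,
        n_replicas=t50s.size)


@dataclass
class ScalingFit:
    """OLS fit of log10(tauRAMD [ns]) on experimental log10(1/k_off [s])."""

    slope: float
    intercept: float
    excluded_outliers: list = field(default_factory=list)
    n_fitted: int = 0
    r2: float = 0.0

    def predict_log_tau(self, tau_ramd_ns) -> np.ndarray:
        """Map relative tauRAMD values (ns) onto the experimental log10(tau [s]) scale."""
        if self.slope == 0:
            raise ValueError("degenerate scaling fit (zero slope)")
        return (np.log10(np.asarray(tau_ramd_ns, float)) - self.intercept) / self.slope

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "excluded_outliers": list(self.excluded_outliers),
            "n_fitted": self.n_fitted, "r2": self.r2}, indent=1))


def fit_scaling(estimates, koffs, exclude=()) -> ScalingFit:
    """Least-squares scaling of relative residence times to experiment.

    ``estimates``: ResidenceEstimate sequence; ``koffs``: mapping
    compound_id -> k_off (s^-1); ``exclude``: outlier compound ids left out
    of the fit (they can still be scaled afterwards).
    """
    exclude = set(exclude)
    xs, ys = [], []
    for est in estimates:
        if est.compound_id in exclude or est.compound_id not in koffs:
            continue
        xs.append(np.log10(1.0 / koffs[est.compound_id]))
        ys.append(np.log10(est.tau_ramd))
    if len(xs) < 3:
        raise ValueError("scaling fit needs at least 3 non-excluded compounds")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs) == 0:
        raise ValueError("degenerate x-variance in scaling fit")
    res = stats.linregress(xs, ys)
    return ScalingFit(slope=float(res.slope), intercept=float(res.intercept),
                      excluded_outliers=sorted(exclude),
                      n_fitted=len(xs), r2=float(res.rvalue ** 2))


#: experimental residence-time bins (s): <1, 1-2, 2-3, >3
_RANGE_EDGES = (0.0, np.log10(2.0), np.log10(3.0))
_RANGE_NAMES = ("<1s", "1s-2s", "2s-3s", ">3s")


@dataclass
class TauEvaluation:
    mae: float
    r2: float
    per_range_mae: dict


def evaluate_tau(predicted_log_tau, observed_log_tau) -> TauEvaluation:
    """MAE, squared Pearson correlation, and per-residence-time-range MAE.

    Both inputs are log10(tau [s]); ranges are bins of the observed
    (experimental) residence time with edges at 1 s, 2 s, and 3 s.
    """
    pred = np.asarray(predicted_log_tau, float)
    obs = np.asarray(observed_log_tau, float)
    if pred.shape != obs.shape:
        raise ValueError("prediction/observation length mismatch")
    err = np.abs(pred - obs)
    r = np.corrcoef(pred, obs)[0, 1] if np.ptp(obs) > 0 and np.ptp(pred) > 0 else 0.0
    bins = np.digitize(obs, _RANGE_EDGES)
    per_range = {}
    for b, name in enumerate(_RANGE_NAMES):
        mask = bins == b
        per_range[name] = float(err[mask].mean()) if mask.any() else float("nan")
    return TauEvaluation(mae=float(err.mean()), r2=float(r ** 2),
                         per_range_mae=per_range)


def clamp_out_of_range(koffs, out_of_range, floor: float = 1e-4):
    """Assign the measurement floor to compounds outside the assay range.

    ``koffs`` in s^-1; entries flagged ``out_of_range`` (residence time
    beyond the measurement limit) are set to ``floor``.
    """
    koffs = np.asarray(koffs, float).copy()
    flags = np.asarray(out_of_range, bool)
    if flags.shape != koffs.shape:
        raise ValueError("flag/value length mismatch")
    if (koffs[~flags] <= 0).any():
        raise ValueError("in-range k_off values must be positive")
    koffs[flags] = floor
    return koffs
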