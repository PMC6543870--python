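"""Bound-state truncation, occurrence averaging, and feature filtering.

A dissociation trajectory's fingerprint stream is split into a bound part
and a transition part. The bound reference is the contact set of the first
frame; the transition part starts at the first frame where enough of those
bound contacts are simultaneously absent. Three truncation rules define the
feature data-sets: A (at least 2 bound contacts lost), B (at least 20 % of
them lost), C (at least 60 % lost). Per-feature occurrences are averaged
over transition frames, then over trajectories per compound, yielding a
compounds x features matrix that is cleaned by a rare-feature filter and a
pairwise-correlation filter and min-max normalized for modelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ramdfp.traj_contacts import IFSeries, _canonical_key

__all__ = [
    "FeatureMatrix",
    "FeaturizeError",
    "TrajectoryProfile",
    "TruncationMode",
    "aggregate_compound",
    "bound_reference",
    "build_matrix",
    "filter_rare",
    "minmax_normalize",
    "prune_correlated",
    "trajectory_occurrence",
    "truncate",
]


class FeaturizeError(ValueError):
    pass


@dataclass(frozen=True)
class TruncationMode:
    """Bound-state truncation rule.

    ``A``: transition starts when >= ``n_lost`` bound contacts are absent;
    ``B``/``C``: when >= ceil(fraction * n_bound) are absent.
    """

    mode: str
    n_lost: int | None = None
    fraction: float | None = None

    def __post_init__(self):
        if self.fraction is not None and not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction threshold must be in (0, 1]")
        if (self.n_lost is None) == (self.fraction is None):
            raise ValueError("exactly one of n_lost / fraction must be set")

    @classmethod
    def A(cls) -> "TruncationMode":
        return cls("A", n_lost=2)

    @classmethod
    def B(cls) -> "TruncationMode":
        return cls("B", fraction=0.20)

    @classmethod
    def C(cls) -> "TruncationMode":
        return cls("C", fraction=0.60)

    @classmethod
    def from_name(cls, name: str) -> "TruncationMode":
        try:
            return {"A": cls.A, "B": cls.B, "C": cls.C}[name.upper()]()
        except KeyError:
            raise ValueError(f"unknown truncation mode {name!r}") from None

    def threshold(self, n_bound: int) -> int:
        if self.n_lost is not None:
            return self.n_lost
        return math.ceil(self.fraction * n_bound)


@dataclass
class TrajectoryProfile:
    """Per-feature occurrence fractions over the transition frames of one trajectory."""

    compound_id: str
    trajectory_id: str
    occurrence: pd.Series
    n_transition_frames: int

    def __post_init__(self):
        occ = self.occurrence.to_numpy(float)
        if ((occ < 0) | (occ > 1)).any():
            raise ValueError("occurrences must lie in [0, 1]")


def bound_reference(series: IFSeries) -> set:
    """Features present in the first (bound-state) frame."""
    if series.n_frames < 1:
        raise FeaturizeError("fingerprint series has no frames")
    present = {n for n, v in zip(series.feature_names, series.frames[0]) if v}
    if not present:
        raise FeaturizeError(
            f"trajectory {series.trajectory_id!r}: no contacts in the first "
            "frame (empty bound state)")
    return present


def truncate(series: IFSeries, mode: TruncationMode) -> IFSeries:
    """Transition part of a fingerprint series under one truncation rule.

    The transition runs from the first frame at which the number of
    bound-reference contacts simultaneously absent meets the rule's
    threshold, through the dissociation frame (inclusive; to the last frame
    for censored trajectories). Later re-formation of contacts does not
    move the start back. An empty result (criterion never met) is returned
    with zero frames and a warning; the caller should exclude it.
    """
    bound = bound_reference(series)
    idx = [i for i, n in enumerate(series.feature_names) if n in bound]
    need = mode.threshold(len(bound))
    absent = len(bound) - series.frames[:, idx].sum(axis=1)
    end = (series.dissociation_frame
           if series.dissociation_frame is not None
           else series.n_frames - 1)
    hits = np.nonzero(absent[:end + 1] >= need)[0]
    if hits.size == 0:
        warnings.warn(
            f"trajectory {series.trajectory_id!r}: truncation criterion "
            f"{mode.mode} never met; empty transition part", stacklevel=2)
        start = end + 1
    else:
        start = int(hits[0])
    return IFSeries(
        compound_id=series.compound_id,
        replica_id=series.replica_id,
        trajectory_id=series.trajectory_id,
        feature_names=list(series.feature_names),
        frames=series.frames[start:end + 1],
        dissociation_frame=series.dissociation_frame,
        frame_times=(None if series.frame_times is None
                     else series.frame_times[start:end + 1]),
    )


def trajectory_occurrence(transition: IFSeries) -> TrajectoryProfile:
    """Fraction of transition frames in which each feature is present."""
    if transition.n_frames < 1:
        raise FeaturizeError(
            f"trajectory {transition.trajectory_id!r} has an empty "
            "transition part")
    occ = transition.frames.mean(axis=0)
    return TrajectoryProfile(
        compound_id=transition.compound_id,
        trajectory_id=transition.trajectory_id,
        occurrence=pd.Series(occ, index=list(transition.feature_names)),
        n_transition_frames=transition.n_frames)


def aggregate_compound(profiles) -> pd.Series:
    """Unweighted mean occurrence per feature over a compound's trajectories.

    Features unseen in a trajectory contribute 0 for that trajectory.
    """
    profiles = list(profiles)
    if not profiles:
        raise FeaturizeError("no trajectory profiles to aggregate")
    ids = {p.compound_id for p in profiles}
    if len(ids) > 1:
        raise FeaturizeError(f"mixed compound ids in aggregation: {sorted(ids)}")
    table = pd.DataFrame([p.occurrence for p in profiles]).fillna(0.0)
    mean = table.mean(axis=0)
    return mean.reindex(sorted(mean.index, key=_canonical_key))


@dataclass
class FeatureMatrix:
    """Compounds x features occurrence matrix with residence-time labels.

    ``labels`` are log10(1/k_off [s]) per compound; ``annotations`` holds
    scaffold/group/outlier flags.
    """

    values: pd.DataFrame
    labels: pd.Series
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        self.labels = self.labels.reindex(self.values.index)
        if self.values.isna().any().any():
            raise FeaturizeError("feature matrix contains missing values")
        if not np.isfinite(self.labels.to_numpy(float)).all():
            raise FeaturizeError("labels must be finite")
        if self.values.index.duplicated().any():
            raise FeaturizeError("duplicate compound ids")
        if self.values.columns.duplicated().any():
            raise FeaturizeError("duplicate feature names")

    @property
    def compound_ids(self):
        return list(self.values.index)

    @property
    def feature_names(self):
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "FeatureMatrix":
        return FeatureMatrix(values, self.labels.copy(),
                             None if self.annotations is None
                             else self.annotations.copy())

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label_log10_inv_koff", self.labels)
        if self.annotations is not None:
            for c in self.annotations.columns:
                out.insert(1, f"annot_{c}", self.annotations[c])
        out.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        table = pd.read_csv(path, index_col="compound_id")
        labels = table.pop("label_log10_inv_koff")
        annot_cols = [c for c in table.columns if c.startswith("annot_")]
        annotations = None
        if annot_cols:
            annotations = table[annot_cols].rename(
                columns=lambda c: c[len("annot_"):])
            table = table.drop(columns=annot_cols)
        return cls(table, labels, annotations)


def build_matrix(profiles_by_compound: dict, labels: pd.Series,
                 annotations: pd.DataFrame | None = None) -> FeatureMatrix:
    """Assemble the compound-level matrix from per-trajectory profiles."""
    rows = {cid: aggregate_compound(profs)
            for cid, profs in profiles_by_compound.items()}
    values = pd.DataFrame(rows).T.fillna(0.0)
    values = values[sorted(values.columns, key=_canonical_key)]
    return FeatureMatrix(values, labels.reindex(values.index),
                         None if annotations is None
                         else annotations.reindex(values.index))


def filter_rare(matrix: FeatureMatrix,
                min_occurrence: float = 0.05) -> FeatureMatrix:
    """Drop features whose occurrence is below ``min_occurrence`` in every compound.

    A feature survives iff its maximum mean occurrence over compounds is at
    least the threshold (boundary inclusive).
    """
    keep = matrix.values.columns[matrix.values.max(axis=0) >= min_occurrence]
    if len(keep) == 0:
        raise FeaturizeError("rare-feature filter removed all features")
    return matrix.with_values(matrix.values[list(keep)])


def prune_correlated(matrix: FeatureMatrix,
                     r2_max: float = 0.9) -> FeatureMatrix:
    """Greedy removal of one feature from every highly correlated pair.

    Features are scanned in canonical order (ascending residue number, then
    HB < ARO < IP < APO); a feature is dropped when its squared Pearson
    correlation with any already-kept feature exceeds ``r2_max``.
    Zero-variance columns have undefined correlation, treated as 0.
    """
    cols = sorted(matrix.values.columns, key=_canonical_key)
    X = matrix.values[cols].to_numpy(float)
    sd = X.std(axis=0)
    centered = X - X.mean(axis=0)
    kept: list[int] = []
    for j in range(X.shape[1]):
        drop = False
        if sd[j] > 0:
            for k in kept:
                if sd[k] == 0:
                    continue
                r = (centered[:, j] @ centered[:, k]) / (
                    len(X) * sd[j] * sd[k])
                if r * r > r2_max:
                    drop = True
                    break
        if not drop:
            kept.append(j)
    keep_names = [cols[j] for j in kept]
    # restore the matrix's own column order
    keep_names = [c for c in matrix.values.columns if c in set(keep_names)]
    return matrix.with_values(matrix.values[keep_names])


def minmax_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Rescale each feature to [0, 1] over all compounds; constant columns map to 0."""
    X = matrix.values
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = (hi - lo).replace(0.0, np.inf)  # constant columns -> 0
    return matrix.with_values((X - lo) / span)
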