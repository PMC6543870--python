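"""Gaussian-mixture clustering of compounds by dissociation fingerprints.

Compounds are clustered in normalized contact-occurrence space with a
Gaussian mixture in which every component carries its own full covariance
matrix. The number of components is chosen by the Akaike information
criterion over a scan range. Clustering is repeated (default 50 times);
within each repeat clusters are ordered by the mean residence time of
their members, and repeats are aggregated by rank, giving per-cluster mean
residence times, feature-weight vectors (the component means), and a
stability score. Fragment occupancy relates cluster membership to
substituent chemistry: the fraction of a cluster's compounds carrying each
annotated fragment class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterEnsemble",
    "GMMFit",
    "fit_gmm",
    "fragment_occupancy",
    "repeat_cluster",
    "select_k_aic",
]


@dataclass
class GMMFit:
    assignments: np.ndarray      # hard assignment per compound
    means: np.ndarray            # (k, n_features) component means
    covariances: np.ndarray      # (k, n_features, n_features)
    aic: float
    converged: bool


def fit_gmm(X, k: int, seed: int = 0, reg_covar: float = 1e-3,
            max_iter: int = 200) -> GMMFit:
    """Maximum-likelihood Gaussian mixture with full per-component covariance.

    Hard assignments are the argmax responsibilities. Non-convergence is
    reported via the ``converged`` flag and a warning with diagnostics.
    The covariance floor ``reg_covar`` (variance units) is set for features
    normalized to [0, 1]: it stops components collapsing onto near-singular
    clumps, which otherwise produces spurious information-criterion minima
    at large component counts.
    """
    X = np.asarray(X, float)
    if X.shape[0] <= k:
        raise ValueError(f"need more compounds ({X.shape[0]}) than clusters ({k})")
    gmm = GaussianMixture(n_components=k, covariance_type="full",
                          random_state=seed, reg_covar=reg_covar,
                          max_iter=max_iter, n_init=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = gmm.fit_predict(X)
    if not gmm.converged_:
        warnings.warn(
            f"GMM(k={k}, seed={seed}) did not converge in {max_iter} "
            f"iterations (lower bound {gmm.lower_bound_:.4g})", stacklevel=2)
    return GMMFit(assignments=labels, means=gmm.means_.copy(),
                  covariances=gmm.covariances_.copy(),
                  aic=float(gmm.aic(X)), converged=bool(gmm.converged_))


def select_k_aic(X, k_range=range(2, 11), seed: int = 0,
                 n_restarts: int = 10):
    """Cluster count minimizing the AIC (best of seeded restarts per k).

    Returns ``(k_best, aic_by_k)``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty cluster-count range")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=(len(k_range), n_restarts))
    aic_by_k = {}
    for i, k in enumerate(k_range):
        aic_by_k[k] = min(fit_gmm(X, k, seed=int(s)).aic for s in seeds[i])
    k_best = min(aic_by_k, key=lambda k: (aic_by_k[k], k))
    return k_best, aic_by_k


@dataclass
class ClusterEnsemble:
    """Repeated, residence-time-ordered GMM clusterings.

    Clusters are matched across repeats by rank (rank 0 = shortest mean
    residence time). ``tau_c`` / ``tau_c_sd`` aggregate the per-repeat
    cluster-mean log residence times; ``feature_weights`` are the mean
    component-mean vectors per rank; ``stability`` is the mean pairwise
    adjusted Rand agreement between repeat assignments.
    """

    n_clusters: int
    compound_ids: list
    feature_names: list
    assignments: np.ndarray      # (repeats, n_compounds) rank labels
    repeat_tau: np.ndarray       # (repeats, k) per-repeat cluster mean label
    repeat_weights: np.ndarray   # (repeats, k, n_features)
    tau_c: np.ndarray = field(init=False)
    tau_c_sd: np.ndarray = field(init=False)
    feature_weights: np.ndarray = field(init=False)
    stability: float = field(init=False)

    def __post_init__(self):
        self.tau_c = self.repeat_tau.mean(axis=0)
        self.tau_c_sd = self.repeat_tau.std(axis=0, ddof=0)
        self.feature_weights = self.repeat_weights.mean(axis=0)
        n = self.assignments.shape[0]
        if n > 1:
            scores = [adjusted_rand_score(self.assignments[i],
                                          self.assignments[j])
                      for i in range(n) for j in range(i + 1, n)]
            self.stability = float(np.mean(scores))
        else:
            self.stability = 1.0

    @property
    def n_repeats(self) -> int:
        return self.assignments.shape[0]

    def cluster_sizes(self, repeat: int = 0) -> np.ndarray:
        return np.bincount(self.assignments[repeat], minlength=self.n_clusters)

    def weights_frame(self) -> pd.DataFrame:
        """Feature weights: rows = features, columns = ordered clusters."""
        return pd.DataFrame(
            self.feature_weights.T, index=self.feature_names,
            columns=[f"cluster_{i + 1}" for i in range(self.n_clusters)])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "n_clusters": self.n_clusters,
            "n_repeats": self.n_repeats,
            "compound_ids": list(self.compound_ids),
            "tau_c": [float(v) for v in self.tau_c],
            "tau_c_sd": [float(v) for v in self.tau_c_sd],
            "stability": self.stability,
            "assignments": self.assignments.tolist()}, indent=1))


def repeat_cluster(matrix_values, labels, k: int, repeats: int = 50,
                   seed: int = 0) -> ClusterEnsemble:
    """Repeat GMM clustering and order clusters by mean residence time.

    ``matrix_values``: normalized compounds x features DataFrame;
    ``labels``: per-compound log10 residence times used for ordering.
    """
    X = matrix_values.to_numpy(float)
    y = pd.Series(labels).reindex(matrix_values.index).to_numpy(float)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=repeats)
    assignments = np.zeros((repeats, len(X)), int)
    repeat_tau = np.zeros((repeats, k))
    repeat_weights = np.zeros((repeats, k, X.shape[1]))
    for r, s in enumerate(seeds):
        fit = fit_gmm(X, k, seed=int(s))
        cluster_tau = np.array([
            y[fit.assignments == c].mean() if (fit.assignments == c).any()
            else np.inf for c in range(k)])
        order = np.argsort(cluster_tau, kind="stable")
        rank_of = np.empty(k, int)
        rank_of[order] = np.arange(k)
        assignments[r] = rank_of[fit.assignments]
        repeat_tau[r] = cluster_tau[order]
        repeat_weights[r] = fit.means[order]
    return ClusterEnsemble(
        n_clusters=k,
        compound_ids=list(matrix_values.index),
        feature_names=list(matrix_values.columns),
        assignments=assignments,
        repeat_tau=repeat_tau,
        repeat_weights=repeat_weights)


def fragment_occupancy(ensemble: ClusterEnsemble,
                       fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster fragment-class occupancy, averaged over repeats.

    ``fragments``: DataFrame indexed by compound id; each column is a
    fragment slot (e.g. solvent-exposed R1, buried R2) with categorical
    class values. Occupancy(cluster, class) = (# members carrying the
    class) / cluster size, averaged over the clustering repeats.
    """
    missing = [c for c in ensemble.compound_ids if c not in fragments.index]
    if missing:
        raise ValueError(f"missing fragment annotations for: {missing}")
    frag = fragments.loc[list(ensemble.compound_ids)]
    columns = [f"{slot}:{cls}" for slot in frag.columns
               for cls in sorted(frag[slot].dropna().astype(str).unique())]
    k = ensemble.n_clusters
    acc = np.zeros((k, len(columns)))
    col_index = {c: i for i, c in enumerate(columns)}
    for rep in range(ensemble.n_repeats):
        ranks = ensemble.assignments[rep]
        for c in range(k):
            members = np.nonzero(ranks == c)[0]
            if members.size == 0:
                continue
            sub = frag.iloc[members]
            for slot in frag.columns:
                counts = sub[slot].dropna().astype(str).value_counts()
                for cls, cnt in counts.items():
                    acc[c, col_index[f"{slot}:{cls}"]] += cnt / members.size
    acc /= ensemble.n_repeats
    return pd.DataFrame(
        acc, index=[f"cluster_{i + 1}" for i in range(k)], columns=columns)
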