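"""QSKR regression protocol: constrained splits, grid search, repeated evaluation.

Models predict log10(1/k_off) from normalized contact-occurrence features.
Each evaluation round (i) draws a constrained train/test split — the test
set is 20 % of the compounds and must contain a fixed number of compounds
from an "outlier" pool (compounds whose residence times are poorly
estimated from trajectory lengths alone) and a minimum number from the
over-represented indazole scaffold pool; (ii) selects hyperparameters by
exhaustive grid search with 10-fold random-permutation cross-validation
(20 % validation); (iii) runs 10 cross-validation fits, scoring MAE and the
external-validation coefficient Q2F3 on the training, validation, and
external test subsets, for ridge linear regression (LR), RBF-kernel support
vector regression (SVR), and a train-mean Dummy control. Rounds are
repeated (default 200) to obtain score distributions and, for LR, averaged
per-feature coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import ShuffleSplit
from sklearn.svm import SVR

from ramdfp.featurize import FeatureMatrix

__all__ = [
    "DEFAULT_GRIDS",
    "EvaluationResult",
    "RoundResult",
    "SplitConstraints",
    "coefficient_summary",
    "fit_predict",
    "grid_search",
    "mae",
    "q2f3",
    "repeated_evaluation",
    "split_train_test",
]

MODELS = ("LR", "SVR", "Dummy")

#: hyperparameter grids (configurable): LR regularization strength; SVR
#: error-term weight C, epsilon-insensitive-loss width, RBF kernel width.
DEFAULT_GRIDS = {
    "LR": {"alpha": np.logspace(-3, 3, 13)},
    "SVR": {"C": np.logspace(-1, 3, 5),
            "epsilon": np.array([0.01, 0.05, 0.1, 0.2]),
            "gamma": np.logspace(-3, 1, 5)},
}


def mae(pred, obs) -> float:
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("prediction/observation length mismatch")
    return float(np.abs(pred - obs).mean())


def q2f3(pred_test, obs_test, obs_train) -> float:
    """External-validation determination coefficient.

    Q2F3 = 1 - [sum_test (y - yhat)^2 / n_test] /
               [sum_train (y - ybar_train)^2 / n_train].
    """
    pred_test = np.asarray(pred_test, float)
    obs_test = np.asarray(obs_test, float)
    obs_train = np.asarray(obs_train, float)
    if pred_test.shape != obs_test.shape:
        raise ValueError("prediction/observation length mismatch")
    denom = float(np.mean((obs_train - obs_train.mean()) ** 2))
    if denom == 0:
        raise ValueError("zero training variance; Q2F3 undefined")
    num = float(np.mean((obs_test - pred_test) ** 2))
    return 1.0 - num / denom


@dataclass(frozen=True)
class SplitConstraints:
    """Composition constraints for the external test set.

    ``outlier_pool``: compounds whose residence time is badly estimated by
    trajectory-length statistics; exactly ``n_outlier_in_test`` of them go
    to the test set. ``indazole_pool``: the over-represented scaffold; at
    least 20 % of that pool (and at least ``min_indazole_floor`` members
    when the pool has 45 or more compounds) must be in the test set.
    Overlapping pools are resolved outlier-first.
    """

    test_fraction: float = 0.20
    n_outlier_in_test: int = 2
    outlier_pool: tuple = ()
    indazole_pool: tuple = ()
    min_indazole_floor: int = 9

    def min_indazole_in_test(self) -> int:
        pool = len(self.indazole_pool)
        if pool == 0:
            return 0
        need = math.ceil(self.test_fraction * pool)
        if pool >= 45:
            need = max(need, self.min_indazole_floor)
        return need

    @classmethod
    def from_annotations(cls, annotations: pd.DataFrame,
                         group_column: str = "group", **kw) -> "SplitConstraints":
        """Pools from an annotation column with values {outlier, indazole, ...}."""
        groups = annotations[group_column].astype(str)
        return cls(
            outlier_pool=tuple(groups.index[groups == "outlier"]),
            indazole_pool=tuple(groups.index[groups == "indazole"]), **kw)


def split_train_test(compound_ids, constraints: SplitConstraints | None = None,
                     seed: int | np.random.Generator = 0):
    """Constrained, seeded train/test split; returns (train_ids, test_ids)."""
    ids = list(compound_ids)
    constraints = constraints or SplitConstraints(
        n_outlier_in_test=0, min_indazole_floor=0)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_test = round(constraints.test_fraction * len(ids))
    outliers = [c for c in constraints.outlier_pool if c in set(ids)]
    n_out = min(constraints.n_outlier_in_test, n_test)
    if len(outliers) < n_out:
        raise ValueError(
            f"outlier pool ({len(outliers)}) smaller than required test "
            f"members ({n_out})")
    test = list(rng.choice(outliers, size=n_out, replace=False)) if n_out else []

    indazoles = [c for c in constraints.indazole_pool
                 if c in set(ids) and c not in set(test)]
    n_ind = constraints.min_indazole_in_test()
    n_ind -= sum(c in set(constraints.indazole_pool) for c in test)
    n_ind = max(0, min(n_ind, n_test - len(test)))
    if len(indazoles) < n_ind:
        raise ValueError(
            f"indazole pool ({len(indazoles)}) smaller than required test "
            f"members ({n_ind})")
    if n_ind:
        test += list(rng.choice(indazoles, size=n_ind, replace=False))

    # the uniform remainder excludes the outlier pool so that the test set
    # contains exactly the prescribed number of outliers
    rest = [c for c in ids
            if c not in set(test) and c not in set(constraints.outlier_pool)]
    n_fill = n_test - len(test)
    if n_fill > 0:
        test += list(rng.choice(rest, size=n_fill, replace=False))
    test_set = set(test)
    train = [c for c in ids if c not in test_set]
    return train, sorted(test, key=ids.index)


def _shuffle_folds(n: int, n_splits: int, val_fraction: float, seed: int):
    splitter = ShuffleSplit(n_splits=n_splits, test_size=val_fraction,
                            random_state=seed)
    return list(splitter.split(np.empty((n, 1))))


def _ridge_cv_mae(X, y, alphas, folds):
    """Mean validation MAE per ridge strength, all alphas from one SVD per fold.

    Numerically identical to fitting sklearn ``Ridge(alpha)`` (with
    intercept) on each fold: with centered data and SVD X = U S V^T, the
    coefficients are V diag(s/(s^2+alpha)) U^T y.
    """
    errs = np.zeros(len(alphas))
    for tr, va in folds:
        Xt, yt = X[tr], y[tr]
        xm, ym = Xt.mean(axis=0), yt.mean()
        U, s, Vt = np.linalg.svd(Xt - xm, full_matrices=False)
        Uty = U.T @ (yt - ym)
        Xva = X[va] - xm
        proj = Xva @ Vt.T          # (n_val, r)
        for a_i, alpha in enumerate(alphas):
            coef_z = (s / (s ** 2 + alpha)) * Uty
            pred = proj @ coef_z + ym
            errs[a_i] += np.abs(pred - y[va]).mean()
    return errs / len(folds)


def grid_search(model_kind: str, X, y, grids=None, seed: int = 0,
                n_splits: int = 10, val_fraction: float = 0.2) -> dict:
    """Exhaustive grid search minimizing mean validation MAE.

    Validation uses ``n_splits`` random-permutation splits with a
    ``val_fraction`` validation subset, shared across all grid points.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) < 10:
        raise ValueError("training set too small for grid search (need >= 10)")
    grid = (grids or DEFAULT_GRIDS).get(model_kind)
    if model_kind == "Dummy":
        return {}
    if grid is None or any(len(v) == 0 for v in grid.values()):
        raise ValueError(f"empty hyperparameter grid for {model_kind!r}")
    folds = _shuffle_folds(len(X), n_splits, val_fraction, seed)
    if model_kind == "LR":
        alphas = np.asarray(grid["alpha"], float)
        errs = _ridge_cv_mae(X, y, alphas, folds)
        return {"alpha": float(alphas[int(np.argmin(errs))])}
    if model_kind == "SVR":
        best, best_err = None, np.inf
        for C in grid["C"]:
            for eps in grid["epsilon"]:
                for gamma in grid["gamma"]:
                    err = 0.0
                    for tr, va in folds:
                        m = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
                        m.fit(X[tr], y[tr])
                        err += np.abs(m.predict(X[va]) - y[va]).mean()
                    err /= len(folds)
                    if err < best_err:
                        best_err = err
                        best = {"C": float(C), "epsilon": float(eps),
                                "gamma": float(gamma)}
        return best
    raise ValueError(f"unknown model kind {model_kind!r}")


def _make_model(model_kind: str, params: dict):
    if model_kind == "LR":
        return Ridge(**params)
    if model_kind == "SVR":
        return SVR(kernel="rbf", **params)
    if model_kind == "Dummy":
        return DummyRegressor(strategy="mean")
    raise ValueError(f"unknown model kind {model_kind!r}")


def fit_predict(model_kind: str, X_train, y_train, X_test, params=None):
    """Fit one model and predict the test set.

    Returns ``(predictions, coefficients)``; coefficients are per-feature
    for LR and ``None`` otherwise.
    """
    params = params or {}
    model = _make_model(model_kind, params)
    model.fit(np.asarray(X_train, float), np.asarray(y_train, float))
    pred = model.predict(np.asarray(X_test, float))
    coefs = model.coef_.copy() if model_kind == "LR" else None
    return pred, coefs


@dataclass
class RoundResult:
    round: int
    model: str
    subset: str          # train / validation / test
    mae: float
    q2f3: float
    hyperparameters: dict = field(default_factory=dict)
    coefficients: np.ndarray | None = None


@dataclass
class EvaluationResult:
    rounds: list
    feature_names: list
    failures: list = field(default_factory=list)

    def scores(self, model: str, subset: str = "test",
               metric: str = "mae") -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.rounds
                         if r.model == model and r.subset == subset])

    def summary(self) -> pd.DataFrame:
        rows = []
        for model in sorted({r.model for r in self.rounds}):
            for subset in ("train", "validation", "test"):
                m = self.scores(model, subset, "mae")
                q = self.scores(model, subset, "q2f3")
                if m.size:
                    rows.append({"model": model, "subset": subset,
                                 "mae_mean": m.mean(), "mae_sd": m.std(ddof=0),
                                 "q2f3_mean": q.mean(), "q2f3_sd": q.std(ddof=0),
                                 "n_rounds": m.size})
        return pd.DataFrame(rows)

    def to_jsonl(self, path) -> None:
        import json
        with open(path, "w") as fh:
            for r in self.rounds:
                rec = {"round": r.round, "model": r.model, "subset": r.subset,
                       "mae": r.mae, "q2f3": r.q2f3,
                       "hyperparameters": r.hyperparameters}
                if r.coefficients is not None:
                    rec["coefficients"] = [float(c) for c in r.coefficients]
                fh.write(json.dumps(rec) + "\n")


def _round_seed(master_seed: int, round_index: int, offset: int = 0) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(round_index), offset])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def repeated_evaluation(matrix: FeatureMatrix,
                        constraints: SplitConstraints | None = None,
                        n_rounds: int = 200, seed: int = 0,
                        models=("LR", "SVR", "Dummy"),
                        grids=None,
                        n_cv_runs: int = 10,
                        tau_predictions: pd.Series | None = None) -> EvaluationResult:
    """Run the full repeated train/test protocol.

    ``tau_predictions``: optional per-compound residence-time predictions
    from trajectory-length statistics (scaled tauRAMD, log10 s); when
    given, they are evaluated on the identical test subsets under the model
    name ``"tauRAMD"``.
    """
    if constraints is None and matrix.annotations is not None \
            and "group" in matrix.annotations.columns:
        constraints = SplitConstraints.from_annotations(matrix.annotations)
    ids = matrix.compound_ids
    X_all = matrix.values
    y_all = matrix.labels
    rounds: list[RoundResult] = []
    failures: list[dict] = []
    for r in range(n_rounds):
        try:
            train_ids, test_ids = split_train_test(
                ids, constraints, np.random.default_rng(_round_seed(seed, r)))
            Xtr = X_all.loc[train_ids].to_numpy(float)
            ytr = y_all.loc[train_ids].to_numpy(float)
            Xte = X_all.loc[test_ids].to_numpy(float)
            yte = y_all.loc[test_ids].to_numpy(float)
            cv_folds = _shuffle_folds(len(Xtr), n_cv_runs, 0.2,
                                      _round_seed(seed, r, 1))
            for model in models:
                params = grid_search(model, Xtr, ytr, grids=grids,
                                     seed=_round_seed(seed, r, 2))
                agg = {s: {"mae": [], "q2f3": []}
                       for s in ("train", "validation", "test")}
                coef_acc = []
                for tr, va in cv_folds:
                    m = _make_model(model, params)
                    m.fit(Xtr[tr], ytr[tr])
                    pred_tr = m.predict(Xtr[tr])
                    pred_va = m.predict(Xtr[va])
                    pred_te = m.predict(Xte)
                    coefs = m.coef_.copy() if model == "LR" else None
                    fit_y = ytr[tr]
                    agg["train"]["mae"].append(mae(pred_tr, ytr[tr]))
                    agg["train"]["q2f3"].append(q2f3(pred_tr, ytr[tr], fit_y))
                    agg["validation"]["mae"].append(mae(pred_va, ytr[va]))
                    agg["validation"]["q2f3"].append(q2f3(pred_va, ytr[va], fit_y))
                    agg["test"]["mae"].append(mae(pred_te, yte))
                    agg["test"]["q2f3"].append(q2f3(pred_te, yte, fit_y))
                    if coefs is not None:
                        coef_acc.append(coefs)
                for subset, vals in agg.items():
                    rounds.append(RoundResult(
                        round=r, model=model, subset=subset,
                        mae=float(np.mean(vals["mae"])),
                        q2f3=float(np.mean(vals["q2f3"])),
                        hyperparameters=params,
                        coefficients=(np.mean(coef_acc, axis=0)
                                      if subset == "test" and coef_acc
                                      else None)))
            if tau_predictions is not None:
                pred_te = tau_predictions.loc[test_ids].to_numpy(float)
                rounds.append(RoundResult(
                    round=r, model="tauRAMD", subset="test",
                    mae=mae(pred_te, yte),
                    q2f3=q2f3(pred_te, yte, ytr)))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            failures.append({"round": r, "error": repr(exc)})
    if failures and not rounds:
        raise RuntimeError(f"all rounds failed; first error: {failures[0]}")
    return EvaluationResult(rounds=rounds, feature_names=matrix.feature_names,
                            failures=failures)


def coefficient_summary(result: EvaluationResult) -> pd.DataFrame:
    """Per-feature mean and SD of LR coefficients across rounds, by |mean|."""
    mats = [r.coefficients for r in result.rounds
            if r.model == "LR" and r.coefficients is not None]
    if not mats:
        raise ValueError("no LR rounds with coefficients")
    arr = np.stack(mats)
    out = pd.DataFrame({
        "feature": result.feature_names,
        "coef_mean": arr.mean(axis=0),
        "coef_sd": arr.std(axis=0, ddof=0)})
    return out.reindex(
        out["coef_mean"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
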