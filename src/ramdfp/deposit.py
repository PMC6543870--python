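"""Loading a deposited per-frame fingerprint data set and its reduction cascade.

A deposit directory is expected to contain one sub-directory per compound
with per-trajectory fingerprint CSVs (rows = frames, columns = (residue,
category) features, plus the JSON metadata sidecars written by
:meth:`ramdfp.traj_contacts.IFSeries.to_csv`), and a ``kinetics.csv`` table
with columns ``compound``, ``koff_s`` and optional ``out_of_range``,
``group`` annotation columns. ``feature_cascade`` reports the feature
counts through the pipeline (raw union -> rare-feature filter ->
correlation filter) for each truncation rule, the figures by which a
fingerprint data set is usually summarized.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ramdfp.featurize import (
    FeaturizeError,
    TruncationMode,
    build_matrix,
    filter_rare,
    minmax_normalize,
    prune_correlated,
    trajectory_occurrence,
    truncate,
)
from ramdfp.tau import clamp_out_of_range
from ramdfp.traj_contacts import IFSeries

__all__ = ["load_deposit", "feature_cascade"]


def load_deposit(root):
    """Read per-compound fingerprint series and the kinetics table.

    Returns ``(series_by_compound, kinetics)`` where ``series_by_compound``
    maps compound id -> list of IFSeries.
    """
    root = Path(root)
    kin_path = root / "kinetics.csv"
    if not kin_path.exists():
        raise FileNotFoundError(f"no kinetics table at {kin_path}")
    kinetics = pd.read_csv(kin_path).set_index("compound")
    series = {}
    for cdir in sorted(p for p in root.iterdir() if p.is_dir()):
        items = [IFSeries.from_csv(p) for p in sorted(cdir.glob("*.csv"))]
        if items:
            series[cdir.name] = items
    if not series:
        raise FileNotFoundError(f"no per-compound fingerprint CSVs under {root}")
    return series, kinetics


def feature_cascade(series_by_compound: dict, kinetics: pd.DataFrame,
                    modes=("A", "B", "C"), min_occurrence: float = 0.05,
                    r2_max: float = 0.9, koff_floor: float = 1e-4):
    """Feature counts raw / after rare filter / after correlation filter per mode.

    Returns ``(counts, matrices)``: ``counts[mode]`` is a dict with keys
    ``raw``, ``rare_filtered``, ``pruned``; ``matrices[mode]`` is the
    final normalized FeatureMatrix.
    """
    koffs = clamp_out_of_range(
        kinetics["koff_s"].to_numpy(float),
        kinetics.get("out_of_range",
                     pd.Series(False, index=kinetics.index)).to_numpy(bool),
        floor=koff_floor)
    labels = pd.Series(np.log10(1.0 / koffs), index=kinetics.index)
    annot_cols = [c for c in kinetics.columns
                  if c not in ("koff_s", "out_of_range")]
    annotations = kinetics[annot_cols] if annot_cols else None
    counts, matrices = {}, {}
    for mode_name in modes:
        mode = TruncationMode.from_name(mode_name)
        profiles = {}
        for cid, series_list in series_by_compound.items():
            profs = []
            for s in series_list:
                try:
                    profs.append(trajectory_occurrence(truncate(s, mode)))
                except FeaturizeError:
                    continue
            if profs:
                profiles[cid] = profs
        matrix = build_matrix(profiles, labels, annotations)
        raw = len(matrix.feature_names)
        rare = filter_rare(matrix, min_occurrence)
        pruned = prune_correlated(rare, r2_max)
        counts[mode_name] = {"raw": raw,
                             "rare_filtered": len(rare.feature_names),
                             "pruned": len(pruned.feature_names)}
        matrices[mode_name] = minmax_normalize(pruned)
    return counts, matrices
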