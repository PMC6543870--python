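"""Bound-state truncation, occurrence aggregation, and feature filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramdfp.featurize import (
    FeatureMatrix,
    FeaturizeError,
    TruncationMode,
    aggregate_compound,
    bound_reference,
    build_matrix,
    filter_rare,
    minmax_normalize,
    prune_correlated,
    trajectory_occurrence,
    truncate,
)
from ramdfp.synthetic import ContactSchedule, gen_if_series, random_contact_schedule
from ramdfp.traj_contacts import IFSeries


def _series(rows, names=None, dissociation=None):
    rows = np.asarray(rows, np.uint8)
    names = names or [f"X{i + 1}-HB" for i in range(rows.shape[1])]
    return IFSeries("c", "r", "t", names, rows, dissociation)


class TestBoundReference:
    def test_first_frame_defines_bound_set(self):
        s = _series([[1, 1, 0], [0, 1, 1]], names=["a", "b", "c"])
        assert bound_reference(s) == {"a", "b"}

    def test_all_ones_first_frame(self):
        s = _series(np.ones((2, 5)))
        assert bound_reference(s) == set(s.feature_names)

    def test_empty_first_frame_errors(self):
        with pytest.raises(FeaturizeError, match="bound"):
            bound_reference(_series([[0, 0], [1, 1]]))


class TestTruncation:
    def test_mode_a_two_contacts_lost(self):
        """Bound {a,b,c}; presence (111),(110),(100),(000): A truncates at frame 2."""
        s = _series([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]],
                    names=["a", "b", "c"])
        out = truncate(s, TruncationMode.A())
        assert out.n_frames == 2
        assert np.array_equal(out.frames, [[1, 0, 0], [0, 0, 0]])

    def test_modes_b_c_fractional_thresholds(self):
        """10 bound contacts lost one per frame: B truncates at 2, C at 6."""
        names = [f"f{i}" for i in range(10)]
        loss = {n: i + 1 for i, n in enumerate(names)}
        s = gen_if_series(ContactSchedule(names, 12, loss))
        assert s.n_frames - truncate(s, TruncationMode.B()).n_frames == 2
        assert s.n_frames - truncate(s, TruncationMode.C()).n_frames == 6

    def test_contacts_never_lost_warns_empty(self):
        s = _series(np.ones((6, 4)))
        with pytest.warns(UserWarning, match="never met"):
            out = truncate(s, TruncationMode.A())
        assert out.n_frames == 0

    def test_transition_ends_at_dissociation_frame(self):
        s = _series([[1, 1], [0, 0], [0, 0], [0, 0]], dissociation=2)
        out = truncate(s, TruncationMode.A())
        assert out.n_frames == 2  # frames 1..2 inclusive

    def test_reformation_does_not_untruncate(self):
        """Contacts regained after the truncation frame do not move it back."""
        s = _series([[1, 1], [0, 0], [1, 1], [0, 0]])
        out = truncate(s, TruncationMode.A())
        assert out.n_frames == 3

    @pytest.mark.parametrize("seed", range(25))
    def test_brute_force_equality_and_ordering(self, seed):
        """Truncation frame equals a brute-force scan; t(A) <= t(B) <= t(C)."""
        s = gen_if_series(random_contact_schedule(seed), seed=seed)
        bound = bound_reference(s)
        idx = [i for i, n in enumerate(s.feature_names) if n in bound]
        end = s.dissociation_frame
        starts = {}
        for mode in (TruncationMode.A(), TruncationMode.B(), TruncationMode.C()):
            need = mode.threshold(len(bound))
            brute = next((f for f in range(end + 1)
                          if len(bound) - s.frames[f, idx].sum() >= need),
                         end + 1)
            out = truncate(s, mode)
            assert end + 1 - out.n_frames == brute
            starts[mode.mode] = brute
        assert starts["A"] <= starts["B"] <= starts["C"]

    def test_invalid_mode_fraction(self):
        with pytest.raises(ValueError):
            TruncationMode("B", fraction=1.5)


class TestOccurrence:
    def test_fraction_of_frames(self):
        rows = np.zeros((12, 1), np.uint8)
        rows[:3, 0] = 1
        prof = trajectory_occurrence(_series(rows))
        assert prof.occurrence.iloc[0] == pytest.approx(0.25)

    def test_always_and_never_present(self):
        rows = np.column_stack([np.ones(5), np.zeros(5)]).astype(np.uint8)
        prof = trajectory_occurrence(_series(rows))
        assert list(prof.occurrence) == [1.0, 0.0]

    def test_empty_transition_errors(self):
        with pytest.raises(FeaturizeError):
            trajectory_occurrence(_series(np.zeros((0, 2), np.uint8)))


class TestAggregation:
    def _profile(self, cid, occ):
        rows = np.zeros((1, len(occ)), np.uint8)
        s = _series(rows, names=list(occ))
        s.compound_id = cid
        prof = trajectory_occurrence(s)
        prof.occurrence = pd.Series(occ)
        return prof

    def test_mean_over_trajectories(self):
        profs = [self._profile("c", {"X1-HB": 0.2}),
                 self._profile("c", {"X1-HB": 0.4})]
        assert aggregate_compound(profs)["X1-HB"] == pytest.approx(0.3)

    def test_unseen_features_count_as_zero(self):
        profs = [self._profile("c", {"X1-HB": 1.0})] + \
            [self._profile("c", {"X2-HB": 0.5}) for _ in range(3)]
        agg = aggregate_compound(profs)
        assert agg["X1-HB"] == pytest.approx(0.25)

    def test_single_trajectory_identity(self):
        agg = aggregate_compound([self._profile("c", {"X1-HB": 0.7})])
        assert agg["X1-HB"] == pytest.approx(0.7)

    def test_mixed_compounds_rejected(self):
        with pytest.raises(FeaturizeError, match="mixed"):
            aggregate_compound([self._profile("c1", {"X1-HB": 1.0}),
                                self._profile("c2", {"X1-HB": 1.0})])


def _matrix(values: np.ndarray, names=None) -> FeatureMatrix:
    names = names or [f"X{i + 1}-HB" for i in range(values.shape[1])]
    ids = [f"c{i}" for i in range(values.shape[0])]
    return FeatureMatrix(pd.DataFrame(values, index=ids, columns=names),
                         pd.Series(np.linspace(-1, 1, len(ids)), index=ids))


class TestFilters:
    def test_rare_feature_dropped_and_boundary_kept(self):
        vals = np.zeros((4, 3))
        vals[:, 0] = 0.04   # below threshold everywhere -> dropped
        vals[0, 1] = 0.05   # boundary -> kept
        vals[0, 2] = 1.0    # strong in one compound -> kept
        out = filter_rare(_matrix(vals))
        assert out.feature_names == ["X2-HB", "X3-HB"]

    def test_all_removed_errors(self):
        with pytest.raises(FeaturizeError):
            filter_rare(_matrix(np.full((3, 2), 0.01)))

    def test_identical_columns_keep_first(self, rng):
        base = rng.random(20)
        vals = np.column_stack([base, rng.random(20), base])
        out = prune_correlated(_matrix(vals))
        assert out.feature_names == ["X1-HB", "X2-HB"]

    def test_orthogonal_columns_all_kept(self):
        vals = np.eye(4)
        out = prune_correlated(_matrix(vals))
        assert len(out.feature_names) == 4

    def test_three_identical_keep_only_first(self, rng):
        base = rng.random(15)
        out = prune_correlated(_matrix(np.column_stack([base] * 3)))
        assert out.feature_names == ["X1-HB"]

    def test_zero_variance_columns_survive(self):
        vals = np.column_stack([np.full(6, 0.5), np.full(6, 0.5),
                                np.arange(6) / 5])
        out = prune_correlated(_matrix(vals))
        assert len(out.feature_names) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_filters_match_brute_force(self, seed):
        """Filter cascade equals an exhaustive max-occurrence + pairwise-R2 scan."""
        rng = np.random.default_rng(seed)
        vals = rng.beta(0.4, 2.0, size=(30, 60))
        # plant duplicates and rare columns
        for j in range(0, 60, 7):
            vals[:, j] = vals[:, (j + 13) % 60]
        vals[:, ::11] *= 0.04 / max(vals[:, ::11].max(), 1e-9)
        m = _matrix(vals)
        out = prune_correlated(filter_rare(m))
        # brute force oracle
        cols = [c for c in m.feature_names
                if m.values[c].max() >= 0.05]
        keep = []
        for c in cols:
            ok = True
            for k in keep:
                x, y = m.values[c], m.values[k]
                if x.std() == 0 or y.std() == 0:
                    continue
                if np.corrcoef(x, y)[0, 1] ** 2 > 0.9:
                    ok = False
                    break
            if ok:
                keep.append(c)
        assert out.feature_names == keep
        # survivors pairwise R2 <= 0.9
        sub = out.values.to_numpy()
        for a in range(sub.shape[1]):
            for b in range(a + 1, sub.shape[1]):
                if sub[:, a].std() == 0 or sub[:, b].std() == 0:
                    continue
                assert np.corrcoef(sub[:, a], sub[:, b])[0, 1] ** 2 <= 0.9 + 1e-12


class TestNormalization:
    def test_closed_form(self):
        out = minmax_normalize(_matrix(np.array([[0.1], [0.3], [0.5]])))
        assert np.allclose(out.values.to_numpy().ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(_matrix(np.full((3, 1), 0.4)))
        assert np.allclose(out.values.to_numpy(), 0.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        vals = np.random.default_rng(seed).random((8, 4))
        once = minmax_normalize(_matrix(vals))
        twice = minmax_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_values_stay_in_unit_interval(self, planted_matrix):
        matrix, _ = planted_matrix
        out = minmax_normalize(matrix)
        assert out.values.to_numpy().min() >= 0.0
        assert out.values.to_numpy().max() <= 1.0


class TestFeatureMatrixIO:
    def test_csv_round_trip(self, planted_matrix, tmp_path):
        matrix, _ = planted_matrix
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.feature_names == matrix.feature_names
        assert np.allclose(back.values, matrix.values)
        assert np.allclose(back.labels, matrix.labels)
        assert (back.annotations["group"] == matrix.annotations["group"]).all()

    def test_build_matrix_orders_canonically(self):
        rows = np.ones((2, 2), np.uint8)
        s = _series(rows, names=["F138-APO", "D93-HB"])
        profs = {"c": [trajectory_occurrence(s)]}
        m = build_matrix(profs, pd.Series({"c": 0.0}))
        assert m.feature_names == ["D93-HB", "F138-APO"]
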