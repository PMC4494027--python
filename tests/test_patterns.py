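import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockmvpa.design import DesignParams, build_session_timeline
from blockmvpa.errors import PatternError
from blockmvpa.patterns import (
    BlockPatterns,
    balance_classes,
    cocktail_subtract,
    concat_patterns,
    detrend_standardize,
    extract_block_patterns,
    filter_guessed,
    prepare_patterns,
    roi_timecourses,
)
from blockmvpa.roi import ROI
from blockmvpa.simulate import NoiseSpec
from tests.conftest import make_run


def make_patterns(X, conditions, sessions, subjective=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    return BlockPatterns(
        X=X,
        conditions=np.asarray(conditions, dtype=object),
        sessions=np.asarray(sessions, dtype=int),
        subjective=np.asarray(
            subjective if subjective is not None else ["guessed"] * n, dtype=object
        ),
        condition_order=("A", "B") if "A" in conditions else None or tuple(dict.fromkeys(conditions)),
    )


class TestDetrendStandardize:
    def test_linear_ramp_maps_to_zeros(self):
        tc = np.arange(50, dtype=float)[:, None] * 3.0 + 7.0
        out = detrend_standardize(tc)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        tc = rng.normal(size=(80, 5)) + np.linspace(0, 4, 80)[:, None]
        out = detrend_standardize(tc)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-10)

    def test_residual_orthogonal_to_time(self):
        rng = np.random.default_rng(1)
        tc = rng.normal(size=(200, 1))
        out = detrend_standardize(tc)[:, 0]
        t = np.arange(200, dtype=float)
        r = np.corrcoef(out, t)[0, 1]
        assert abs(r) < 1e-10

    def test_too_short_session_rejected(self):
        with pytest.raises(PatternError):
            detrend_standardize(np.zeros((2, 3)))


class TestExtractBlockPatterns:
    def _single_block_events(self):
        import pandas as pd

        from blockmvpa.design import EventTable

        frame = pd.DataFrame(
            [
                dict(onset=0.0, duration=10.0, trial_type="sentences", session=0,
                     block_id=0, subjective="guessed", objective_correct="true"),
            ]
        )
        return EventTable(frame)

    def test_lagged_window_average(self):
        ev = self._single_block_events()
        tc = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 99.0])[:, None]
        pat = extract_block_patterns(tc, ev, tr_s=2.5, lag_trs=3)
        assert pat.X[0, 0] == pytest.approx(2.5)

    def test_lag_zero_vs_three_impulse_membership(self):
        ev = self._single_block_events()
        tc = np.zeros((10, 1))
        tc[0, 0] = 40.0  # impulse at the onset volume
        with_lag0 = extract_block_patterns(tc, ev, tr_s=2.5, lag_trs=0)
        with_lag3 = extract_block_patterns(tc, ev, tr_s=2.5, lag_trs=3)
        assert with_lag0.X[0, 0] == pytest.approx(10.0)
        assert with_lag3.X[0, 0] == 0.0

    def test_window_overrun_names_block(self):
        ev = self._single_block_events()
        tc = np.zeros((5, 1))
        with pytest.raises(PatternError, match="block 0"):
            extract_block_patterns(tc, ev, tr_s=2.5, lag_trs=3)

    def test_one_row_per_block(self, default_params, labeled_events):
        run = make_run(labeled_events, (2, 2, 1), default_params,
                       noise=NoiseSpec(seed=0))
        pat = extract_block_patterns(
            run.data.reshape(-1, 88).T, labeled_events, tr_s=2.5, lag_trs=3
        )
        assert pat.n_blocks == 12
        assert pat.n_voxels == 4


class TestCocktailSubtract:
    def test_worked_example(self):
        pat = make_patterns(
            [[1.0, 3.0], [3.0, 5.0], [10.0, 10.0], [20.0, 20.0]],
            ["A", "A", "B", "B"],
            [0, 0, 0, 0],
        )
        out = cocktail_subtract(pat)
        np.testing.assert_allclose(out.X[:2], [[-2.0, 0.0], [0.0, 2.0]])

    def test_shift_invariance(self):
        pat = make_patterns(
            [[1.0, 3.0], [3.0, 5.0], [0.0, 1.0], [1.0, 0.0]],
            ["A", "A", "B", "B"],
            [0, 0, 0, 0],
        )
        shifted = pat.take(np.arange(4))
        shifted.X = shifted.X.copy()
        shifted.X[:2] += 42.0  # constant added to every condition-A value
        np.testing.assert_allclose(
            cocktail_subtract(pat).X, cocktail_subtract(shifted).X, atol=1e-12
        )

    def test_conditions_differing_by_offset_become_identical(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 4))
        XA = base
        XB = base + 7.5  # pure global offset
        pat = make_patterns(
            np.vstack([XA, XB]), ["A"] * 3 + ["B"] * 3, [0] * 6
        )
        out = cocktail_subtract(pat)
        np.testing.assert_allclose(out.X[:3], out.X[3:], atol=1e-12)

    def test_session_missing_condition_rejected(self):
        pat = make_patterns([[1.0], [2.0]], ["A", "A"], [0, 0])
        with pytest.raises(PatternError, match="lacks"):
            cocktail_subtract(pat)

    def test_per_session_grand_mean_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        conds = (["A"] * 3 + ["B"] * 3) * 2
        sess = [0] * 6 + [1] * 6
        out = cocktail_subtract(make_patterns(X, conds, sess))
        for s in (0, 1):
            for c in ("A", "B"):
                sel = (out.sessions == s) & (out.conditions == c)
                assert abs(out.X[sel].mean()) < 1e-10

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_grand_mean_zero_property(self, seed):
        rng = np.random.default_rng(seed)
        n_sess = rng.integers(1, 4)
        X, conds, sess = [], [], []
        for s in range(n_sess):
            for c in ("A", "B"):
                k = rng.integers(1, 5)
                X.append(rng.normal(size=(k, 3)) * 10)
                conds += [c] * k
                sess += [s] * k
        out = cocktail_subtract(make_patterns(np.vstack(X), conds, sess))
        for s in range(n_sess):
            for c in ("A", "B"):
                sel = (out.sessions == s) & (out.conditions == c)
                assert abs(out.X[sel].mean()) < 1e-10

    def test_per_voxel_variant_zeroes_mean_pattern(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        pat = make_patterns(X, ["A"] * 3 + ["B"] * 3, [0] * 6)
        out = cocktail_subtract(pat, per_voxel=True)
        np.testing.assert_allclose(out.X[:3].mean(axis=0), 0.0, atol=1e-12)


class TestFilterGuessed:
    def test_counts(self):
        pat = make_patterns(
            np.zeros((12, 2)), ["A"] * 6 + ["B"] * 6, [0] * 12,
            subjective=["guessed"] * 10 + ["knew"] * 2,
        )
        assert filter_guessed(pat).n_blocks == 10

    def test_all_guessed_identity(self):
        pat = make_patterns(np.zeros((4, 2)), ["A", "A", "B", "B"], [0] * 4)
        out = filter_guessed(pat)
        np.testing.assert_array_equal(out.X, pat.X)

    def test_all_knew_rejected(self):
        pat = make_patterns(
            np.zeros((4, 2)), ["A", "A", "B", "B"], [0] * 4,
            subjective=["knew"] * 4,
        )
        with pytest.raises(PatternError):
            filter_guessed(pat)


class TestBalanceClasses:
    def test_discards_down_to_smaller_class(self):
        pat = make_patterns(
            np.arange(36).reshape(18, 2), ["A"] * 10 + ["B"] * 8, [0] * 18
        )
        out = balance_classes(pat, seed=0)
        assert (out.conditions == "A").sum() == 8
        assert (out.conditions == "B").sum() == 8

    def test_already_balanced_identity(self):
        pat = make_patterns(np.zeros((6, 2)), ["A"] * 3 + ["B"] * 3, [0] * 6)
        out = balance_classes(pat, seed=1)
        assert out.n_blocks == 6

    def test_seed_reproducible(self):
        pat = make_patterns(
            np.arange(40).reshape(20, 2), ["A"] * 12 + ["B"] * 8, [0] * 20
        )
        a = balance_classes(pat, seed=9)
        b = balance_classes(pat, seed=9)
        np.testing.assert_array_equal(a.X, b.X)

    def test_empty_condition_rejected(self):
        pat = make_patterns(np.zeros((3, 2)), ["A"] * 3, [0] * 3)
        pat.condition_order = ("A", "B")
        with pytest.raises(PatternError):
            balance_classes(pat, seed=0)


class TestPreparePatterns:
    def _subject(self, n_sessions=3, seed=0):
        p = DesignParams()
        from blockmvpa.simulate import AwarenessModel, simulate_awareness

        runs, evs = [], []
        for s in range(n_sessions):
            ev = build_session_timeline(p, seed=seed * 100 + s, session_id=s)
            ev = simulate_awareness(
                ev,
                AwarenessModel(p_guessed={"sentences": 1.0, "nonwords": 1.0}),
                seed=seed * 200 + s,
            )
            runs.append(
                make_run(ev, (3, 3, 2), p, noise=NoiseSpec(seed=seed * 300 + s))
            )
            evs.append(ev)
        return runs, evs, p

    def test_shapes_and_balance(self):
        runs, evs, p = self._subject()
        roi = ROI(name="r", voxels=np.argwhere(np.ones((3, 3, 2), bool))[:5])
        pat = prepare_patterns(runs, evs, roi, lag_trs=3, balance_seed=0)
        assert pat.n_voxels == 5
        assert (pat.conditions == "sentences").sum() == (pat.conditions == "nonwords").sum()

    def test_no_leakage_across_sessions(self):
        # perturbing one session's data leaves other sessions' rows unchanged
        runs, evs, p = self._subject()
        roi = ROI(name="r", voxels=np.argwhere(np.ones((3, 3, 2), bool))[:5])
        base = prepare_patterns(runs, evs, roi, lag_trs=3, balance_seed=0)
        runs2 = [r for r in runs]
        from blockmvpa.simulate import BoldRun

        perturbed = runs[2].data.copy()
        perturbed += 55.0
        runs2[2] = BoldRun(data=perturbed, tr_s=runs[2].tr_s,
                           voxel_size_mm=runs[2].voxel_size_mm)
        alt = prepare_patterns(runs2, evs, roi, lag_trs=3, balance_seed=0)
        keep = base.sessions != 2
        np.testing.assert_allclose(base.X[keep], alt.X[keep], atol=1e-9)

    def test_session_losing_a_condition_is_dropped(self):
        from blockmvpa.patterns import drop_incomplete_sessions

        pat = make_patterns(
            np.zeros((6, 2)),
            ["A", "B", "A", "B", "A", "A"],
            [0, 0, 1, 1, 2, 2],  # session 2 has no B blocks
        )
        out = drop_incomplete_sessions(pat)
        assert set(out.sessions) == {0, 1}

    def test_all_sessions_incomplete_rejected(self):
        from blockmvpa.patterns import drop_incomplete_sessions

        pat = make_patterns(np.zeros((2, 2)), ["A", "A"], [0, 1])
        pat.condition_order = ("A", "B")
        with pytest.raises(PatternError):
            drop_incomplete_sessions(pat)

    def test_mismatched_lists_rejected(self):
        runs, evs, _ = self._subject()
        roi = ROI(name="r", voxels=np.array([[0, 0, 0]]))
        with pytest.raises(PatternError):
            prepare_patterns(runs[:2], evs, roi)


class TestRoiTimecourses:
    def test_extracts_expected_voxels(self, default_params, default_events):
        run = make_run(default_events, (3, 3, 2), default_params,
                       noise=NoiseSpec(seed=4))
        roi = ROI(name="r", voxels=np.array([[0, 0, 0], [2, 2, 1]]))
        tc = roi_timecourses(run, roi)
        assert tc.shape == (88, 2)
        np.testing.assert_array_equal(tc[:, 0], run.data[0, 0, 0])
        np.testing.assert_array_equal(tc[:, 1], run.data[2, 2, 1])
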