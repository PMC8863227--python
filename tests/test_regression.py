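import numpy as np
import pytest
from scipy import stats

from emgau import regression as rg
from emgau.alignment import AlignedSession
from emgau.io import TriggerEvent, TriggerList


def _ols_oracle(y, X):
    """Independent normal-equations + textbook-formula computation."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    fitted = Xd @ beta
    ssr = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - ssr / sst
    f = (sst - ssr) / p / (ssr / (n - p - 1))
    pval = float(stats.f.sf(f, p, n - p - 1))
    return beta, r2, f, pval, ssr / (n - p - 1)


# ---------------------------------------------------------------------------
# fit_mlr

def test_exact_linear_fit():
    x = np.arange(10.0)
    res = rg.fit_mlr(2 + 3 * x, x)
    assert res.intercept == pytest.approx(2.0, abs=1e-10)
    assert res.slopes[0] == pytest.approx(3.0, abs=1e-10)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.error_variance == pytest.approx(0.0, abs=1e-18)


@pytest.mark.parametrize("seed", range(20))
def test_ols_matches_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 200))
    p = int(rng.integers(1, 10))
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n) + X @ rng.standard_normal(p)
    res = rg.fit_mlr(y, X)
    beta, r2, f, pval, ev = _ols_oracle(y, X)
    np.testing.assert_allclose(np.concatenate([[res.intercept], res.slopes]), beta, rtol=1e-8)
    assert res.r_squared == pytest.approx(r2, rel=1e-8)
    assert res.f_statistic == pytest.approx(f, rel=1e-8)
    assert res.f_pvalue == pytest.approx(pval, rel=1e-6, abs=1e-300)
    assert res.error_variance == pytest.approx(ev, rel=1e-8)


def test_constant_dependent_convention(rng):
    res = rg.fit_mlr(np.full(50, 2.0), rng.standard_normal((50, 3)))
    np.testing.assert_allclose(res.slopes, 0.0, atol=1e-12)
    assert res.r_squared == 0.0
    assert res.f_statistic == 0.0


def test_insufficient_observations_rejected(rng):
    with pytest.raises(rg.InsufficientDataError):
        rg.fit_mlr(np.zeros(4), rng.standard_normal((4, 3)))


def test_fitted_plus_residual_is_observed(rng):
    y = rng.standard_normal(80)
    res = rg.fit_mlr(y, rng.standard_normal((80, 4)))
    np.testing.assert_allclose(res.fitted + res.residuals, y, atol=1e-12)


def test_rank_deficient_design_warns(rng):
    X = rng.standard_normal((50, 2))
    X = np.column_stack([X, X[:, 0] + X[:, 1]])
    with pytest.warns(UserWarning, match="rank-deficient"):
        rg.fit_mlr(rng.standard_normal(50), X)


def test_r2_never_decreases_with_added_regressor(rng):
    y = rng.standard_normal(100)
    X = rng.standard_normal((100, 5))
    r2 = [rg.fit_mlr(y, X[:, : k + 1]).r_squared for k in range(5)]
    assert np.all(np.diff(r2) >= -1e-12)


# ---------------------------------------------------------------------------
# cross-reconstruction on aligned sessions

def _session(ic_tracks, au_tracks, triggers=None):
    return AlignedSession(30.0, ic_tracks, au_tracks, triggers)


def test_ic_identical_to_au_reconstructs_exactly(rng):
    x = np.abs(rng.standard_normal(400))
    others = {a: np.abs(rng.standard_normal(400)) for a in (4, 9)}
    session = _session({"II": x}, {6: x, **others})
    res = rg.reconstruct_ic_from_aus(session, "II")
    wt = rg.build_weight_table([res])
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)
    assert wt.values[0][wt.col_ids.index(6)] == pytest.approx(1.0)


def test_independent_noise_au_has_negligible_r2(rng):
    n = 3600
    ics = {f"IC{k}": np.abs(rng.standard_normal(n)) for k in range(6)}
    session = _session(ics, {6: np.abs(rng.standard_normal(n))})
    res = rg.reconstruct_au_from_ics(session, 6)
    assert res.r_squared <= 0.1


def test_missing_ids_raise():
    session = _session({"II": np.zeros(40)}, {6: np.zeros(40)})
    with pytest.raises(KeyError):
        rg.reconstruct_au_from_ics(session, 12)
    with pytest.raises(KeyError):
        rg.reconstruct_ic_from_aus(session, "IX")


# ---------------------------------------------------------------------------
# weight tables

def test_weight_table_normalization():
    res = rg.RegressionResult("AU6", ["a", "b", "c"], 0.0, np.array([2.0, -4.0, 1.0]),
                              np.zeros(3), np.zeros(3), 1.0, 1.0, 0.0, 0.0, 3)
    wt = rg.build_weight_table([res])
    np.testing.assert_allclose(wt.values[0], [0.5, 1.0, 0.25])


def test_weight_table_column_permutation_equivariance(rng):
    slopes = rng.standard_normal(5)
    mk = lambda ids, s: rg.RegressionResult("y", list(ids), 0.0, np.asarray(s),
                                            np.zeros(3), np.zeros(3), 1.0, 1.0, 0.0, 0.0, 3)
    wt = rg.build_weight_table([mk("abcde", slopes)])
    perm = [2, 0, 4, 1, 3]
    wt_p = rg.build_weight_table([mk([list("abcde")[i] for i in perm], slopes[perm])])
    np.testing.assert_allclose(wt_p.values[0], wt.values[0][perm])


def test_weight_table_argmax_matches_raw_slopes(rng):
    slopes = rng.standard_normal(8)
    res = rg.RegressionResult("y", list(range(8)), 0.0, slopes,
                              np.zeros(3), np.zeros(3), 1.0, 1.0, 0.0, 0.0, 3)
    wt = rg.build_weight_table([res])
    assert np.argmax(wt.values[0]) == np.argmax(np.abs(slopes))


def test_weight_table_zero_row_warns():
    res = rg.RegressionResult("y", ["a"], 0.0, np.array([0.0]),
                              np.zeros(3), np.zeros(3), 0.0, 0.0, 1.0, 0.0, 3)
    with pytest.warns(UserWarning, match="all-zero"):
        wt = rg.build_weight_table([res])
    np.testing.assert_allclose(wt.values[0], 0.0)


# ---------------------------------------------------------------------------
# smile segmentation

def _smile_session(seg_levels, baseline=0.1, on=2.0, gap=4.0, fr=30.0):
    """Track with one burst per trigger at the given plateau levels."""
    events = []
    t = 4.0
    n = int(fr * (4.0 + len(seg_levels) * (on + gap)))
    track = np.full(n, baseline)
    for i, lev in enumerate(seg_levels):
        events.append(TriggerEvent(f"smile {i+1}", t, t + on))
        track[int(t * fr):int((t + on) * fr)] = lev
        t += on + gap
    return _session({"XIII": track}, {12: track.copy()}, TriggerList(events))


def test_flat_tracks_yield_no_segments():
    session = _smile_session([0.1, 0.1, 0.1])  # bursts equal baseline
    assert rg.segment_smiles(session, "XIII") == []


def test_decreasing_amplitudes_preserve_order():
    levels = np.linspace(2.0, 0.6, 8)
    session = _smile_session(list(levels))
    segs = rg.segment_smiles(session, "XIII")
    assert len(segs) == 8
    onsets = [s.onset for s in segs]
    assert onsets == sorted(onsets)  # generation order = amplitude order
    snrs = [s.snr for s in segs]
    assert snrs == sorted(snrs, reverse=True)


def test_burst_below_snr_threshold_excluded():
    # middle burst at only 1.2x the baseline RMS
    session = _smile_session([2.0, 0.12, 2.0])
    segs = rg.segment_smiles(session, "XIII", snr_threshold=1.25)
    assert len(segs) == 2
    assert all(s.snr > 1.25 for s in segs)


def test_segments_carry_track_summaries():
    session = _smile_session([2.0])
    (seg,) = rg.segment_smiles(session, "XIII")
    assert set(seg.fbb_rms) == {"XIII"}
    assert set(seg.au_means) == {12}
    assert seg.fbb_rms["XIII"] > 0


def test_no_triggers_yields_empty_list(rng):
    session = _session({"XIII": np.abs(rng.standard_normal(100))},
                       {12: np.abs(rng.standard_normal(100))})
    assert rg.segment_smiles(session, "XIII") == []
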