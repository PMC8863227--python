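import numpy as np
import pytest
from scipy import signal as sps

from emgau import synthetic as syn
from emgau.alignment import resample_track, rms_envelope


# ---------------------------------------------------------------------------
# calibration protocol

def test_calibration_protocol_three_reps():
    tl = syn.make_calibration_protocol(n_reps=3)
    assert len(tl) == 18
    labels = [e.label for e in tl]
    # each expression appears 3 times, consecutively
    for expr in syn.EXPRESSIONS:
        idx = [i for i, l in enumerate(labels) if l == expr]
        assert len(idx) == 3 and idx == list(range(idx[0], idx[0] + 3))


def test_calibration_protocol_single_rep_span():
    tl = syn.make_calibration_protocol(n_reps=1)
    assert len(tl) == 6
    # 6 expressions x (3 s on + 3 s off) = 36 s protocol cycle
    assert tl.events[-1].onset == 30.0 and tl.span == 33.0


def test_protocol_timing_structure():
    tl = syn.make_calibration_protocol(n_reps=2)
    onsets = np.array([e.onset for e in tl])
    offsets = np.array([e.offset for e in tl])
    assert np.all(np.diff(onsets) > 0)
    np.testing.assert_allclose(offsets - onsets, 3.0)
    np.testing.assert_allclose(onsets[1:] - offsets[:-1], 3.0)  # 3 s gaps


def test_protocol_requires_positive_reps():
    with pytest.raises(ValueError):
        syn.make_calibration_protocol(n_reps=0)


# ---------------------------------------------------------------------------
# sEMG synthesis

def _quiet_noise():
    return syn.NoiseSpec(powerline_harmonics=(0.0,), one_over_f_amp=0.0, white_sigma=0.0)


def test_noiseless_mixing_identity():
    tl = syn.make_calibration_protocol(1)
    sources = syn._calibration_sources(tl)
    rec, truth = syn.synthesize_semg(sources, noise=_quiet_noise(), seed=3)
    np.testing.assert_allclose(rec.samples, truth.mixing @ truth.sources, atol=1e-10)


def test_powerline_only_gives_pure_comb():
    spec = syn.SourceSpec("s", (0.5, 0.5), events=[(1.0, 1.0, 0.0)])
    noise = syn.NoiseSpec(powerline_harmonics=(1.0,), one_over_f_amp=0.0, white_sigma=0.0)
    rec, _ = syn.synthesize_semg([spec], noise=noise, fs=3000.0, duration=4.0, seed=0)
    f, p = sps.periodogram(rec.samples[5], fs=3000.0)
    assert f[np.argmax(p)] == pytest.approx(50.0, abs=f[1] - f[0])
    # essentially all power at the line frequency
    assert p.max() / p.sum() > 0.99


def test_powerline_psd_peak_within_one_bin():
    rec, _, _ = syn.generate_session(syn.default_session_config(n_reps=1), seed=2)
    f, p = sps.welch(rec.samples[0], fs=rec.fs, nperseg=3000)
    band = (f >= 40) & (f <= 60)
    peak = f[band][np.argmax(p[band])]
    assert abs(peak - 50.0) <= f[1] - f[0]


def test_source_center_outside_frame_rejected():
    bad = syn.SourceSpec("s", (1.2, 0.5), events=[(0.0, 1.0, 1.0)])
    with pytest.raises(ValueError, match="center"):
        syn.synthesize_semg([bad], duration=2.0)


def test_mixing_matrix_is_gaussian_in_distance():
    tl = syn.make_calibration_protocol(1)
    sources = syn._calibration_sources(tl)
    rec, truth = syn.synthesize_semg(sources, noise=_quiet_noise(), seed=0)
    k = 2
    d2 = np.sum((rec.layout.coords - np.asarray(sources[k].center)) ** 2, axis=1)
    np.testing.assert_allclose(truth.mixing[:, k], np.exp(-d2 / (2 * sources[k].spread**2)))


# ---------------------------------------------------------------------------
# AU synthesis

def _tiny_truth(seed=0, n_src=2):
    tl = syn.make_calibration_protocol(1)
    sources = syn._calibration_sources(tl)[:n_src]
    _, truth = syn.synthesize_semg(sources, noise=_quiet_noise(), seed=seed)
    return truth


def test_identity_weights_reproduce_envelopes():
    truth = _tiny_truth()
    aus = syn.synthesize_aus(truth, np.eye(2), sigma_au=0.0, seed=0, au_ids=(6, 12))
    env = truth.source_envelopes()
    np.testing.assert_allclose(aus.tracks[6], np.clip(env[0], 0, 5), atol=1e-12)
    np.testing.assert_allclose(aus.tracks[12], np.clip(env[1], 0, 5), atol=1e-12)


def test_weighted_combination_exact():
    truth = _tiny_truth()
    G = np.array([[0.7, 0.3]])
    aus = syn.synthesize_aus(truth, G, sigma_au=0.0, seed=0, au_ids=(6,))
    env = truth.source_envelopes()
    np.testing.assert_allclose(aus.tracks[6], np.clip(G @ env, 0, 5)[0], atol=1e-10)


def test_au_envelope_uses_pipeline_rms_operation():
    truth = _tiny_truth()
    aus = syn.synthesize_aus(truth, np.eye(2), sigma_au=0.0, seed=0, au_ids=(6, 12))
    manual = resample_track(rms_envelope(truth.sources[0], 800), truth.fs, 30.0)
    np.testing.assert_allclose(aus.tracks[6], np.clip(manual, 0, 5), atol=1e-12)


def test_au_weight_shape_mismatch_rejected():
    truth = _tiny_truth()
    with pytest.raises(ValueError, match="column per source"):
        syn.synthesize_aus(truth, np.ones((3, 5)))


def test_crosstalk_fixture_plants_single_path():
    cfg = syn.crosstalk_session_config(crosstalk=0.5)
    idx = {au: i for i, au in enumerate(cfg.au_ids)}
    col = cfg.G[:, 0]  # big-smile (Zygomaticus-like) source
    assert col[idx[6]] == 0.5
    assert np.count_nonzero(col) == 1  # eye-region AU is its only readout


# ---------------------------------------------------------------------------
# full sessions

def test_session_determinism():
    cfg = syn.default_session_config(n_reps=1)
    rec1, aus1, _ = syn.generate_session(cfg, seed=11)
    rec2, aus2, _ = syn.generate_session(cfg, seed=11)
    assert np.array_equal(rec1.samples, rec2.samples)
    for a in aus1.au_ids:
        assert np.array_equal(aus1.tracks[a], aus2.tracks[a])


def test_different_seeds_differ():
    cfg = syn.default_session_config(n_reps=1)
    rec1, _, _ = syn.generate_session(cfg, seed=11)
    rec2, _, _ = syn.generate_session(cfg, seed=12)
    assert not np.allclose(rec1.samples, rec2.samples)


def test_session_durations_consistent(short_session):
    rec, aus, truth = short_session
    assert abs(rec.duration - aus.duration) <= 1.0 / aus.frame_rate


def test_default_session_shape(short_session):
    rec, aus, truth = short_session
    assert rec.n_channels == 16
    assert len(aus.au_ids) == 17
    assert truth.sources.shape[0] == 6


def test_one_over_f_noise_slope(rng):
    from emgau.ica import compute_psd

    x = syn._one_over_f_noise(rng, 60000, alpha=1.0)
    prof = compute_psd(x, fs=3000.0)
    assert prof.one_over_f_slope == pytest.approx(-1.0, abs=0.2)
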