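import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from emgau import ica as ic
from emgau import preprocessing as pp
from emgau import synthetic as syn


@pytest.fixture(autouse=True)
def _silence_ica_convergence():
    # the noise subspace of a 16-channel session never satisfies the strict
    # FastICA tolerance; the warning is expected and documented
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def short_session():
    """One-repetition calibration session (36 s): cheap shared input."""
    cfg = syn.default_session_config(n_reps=1)
    return syn.generate_session(cfg, seed=7)


@pytest.fixture(scope="session")
def short_components(short_session):
    """Classified ICA decomposition of the short session, with truth match."""
    rec, aus, truth = short_session
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        filt = pp.preprocess(rec)
        cs = ic.classify_components(ic.fit_ica(filt, seed=7))
    true_filt = pp.preprocess_matrix(truth.sources, truth.fs)
    match, corrs = ic.match_components_to_sources(cs, true_filt)
    return cs, match, corrs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
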