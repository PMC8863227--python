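"""FastICA unmixing and PSD-based component triage.

The filtered multichannel recording x is decomposed into maximally
independent components s = W x (FastICA, log-cosh contrast, symmetric
decorrelation); the inverse weights A = W^-1 give each component's spatial
loading on the array.  Each component's Welch power spectral density is
then scored against three acceptance criteria for genuine sEMG:

1. most of its power lies in the typical sEMG band (25-300 Hz);
2. no harmonic comb (periodically repeating peaks, e.g. powerline);
3. no strong 1/f trend (motion / electrode drift).

The criteria are qualitative in origin; the thresholds here are package
defaults, exposed through :class:`TriageThresholds`.  Because the
conditioning chain removes essentially everything below 20 Hz, the 1/f
criterion is judged by the log-log PSD slope *inside* the passband
(25-250 Hz by default), where shaped 1/f noise keeps its -alpha slope
while band-limited sEMG is approximately flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import Recording

__all__ = [
    "DecompositionError",
    "ComponentSet",
    "SpectralProfile",
    "TriageThresholds",
    "fit_ica",
    "compute_psd",
    "classify_component",
    "classify_components",
    "amari_index",
    "match_components_to_sources",
]


class DecompositionError(RuntimeError):
    """FastICA failed to converge after all restarts."""


@dataclass
class ComponentSet:
    """ICA decomposition of one recording.

    ``sources`` are unit-variance component time courses (components x
    time); ``W`` the unmixing matrix (s = W (x - mean)); ``A = W^-1`` the
    inverse-weight (mixing) matrix whose columns are the components'
    spatial signatures.  Labels, criterion flags and facial-building-block
    assignments are filled by the triage and mapping stages.
    """

    sources: np.ndarray  # (K, T)
    W: np.ndarray  # (K, C)
    A: np.ndarray  # (C, K)
    mean: np.ndarray  # (C,)
    fs: float
    labels: list[str] = field(default_factory=list)  # semg | noise | unclassified
    flags: list[dict | None] = field(default_factory=list)
    fbb_ids: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = self.sources.shape[0]
        if not self.labels:
            self.labels = ["unclassified"] * k
        if not self.flags:
            self.flags = [None] * k
        if not self.fbb_ids:
            self.fbb_ids = [None] * k

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def semg_indices(self) -> list[int]:
        return [k for k, lab in enumerate(self.labels) if lab == "semg"]

    def permuted(self, order: np.ndarray) -> "ComponentSet":
        """A copy with components reordered by ``order``."""
        order = np.asarray(order, int)
        return ComponentSet(
            self.sources[order],
            self.W[order],
            self.A[:, order],
            self.mean.copy(),
            self.fs,
            [self.labels[i] for i in order],
            [self.flags[i] for i in order],
            [self.fbb_ids[i] for i in order],
        )


@dataclass
class SpectralProfile:
    """Welch PSD of one component plus the triage scores derived from it."""

    frequencies: np.ndarray
    power: np.ndarray
    band_fraction_25_300: float
    harmonic_score: float  # number of comb-aligned prominent peaks
    one_over_f_slope: float  # log-log slope inside the fit band


@dataclass
class TriageThresholds:
    """Acceptance thresholds for the three sEMG criteria (package defaults)."""

    band: tuple[float, float] = (25.0, 300.0)
    min_band_fraction: float = 0.92
    harmonic_min_peaks: int = 3  # comb-aligned prominent peaks that reject
    harmonic_prominence_db: float = 6.0
    harmonic_tol_hz: float = 2.0
    slope_fit_band: tuple[float, float] = (25.0, 250.0)
    min_slope: float = -0.6  # log-log slopes below this flag a 1/f component


def fit_ica(
    rec: Recording,
    n_components: int | None = None,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    restarts: int = 5,
    fit_samples: int = 40000,
    strict: bool = False,
) -> ComponentSet:
    """FastICA decomposition of a filtered recording.

    Uses the log-cosh contrast with symmetric decorrelation and
    unit-variance whitening; deterministic for a fixed seed.

    The unmixing matrix is estimated on a time-decimated view of at most
    ``fit_samples`` samples and then applied to the full recording.
    FastICA treats samples as exchangeable draws, so regular decimation
    changes nothing statistically while keeping long recordings cheap to
    unmix; the returned sources are full length and renormalized to unit
    variance over the whole recording.

    Full convergence of the symmetric fixed-point iteration is generally
    unattainable when some whitened directions are essentially Gaussian
    (pure sensor noise): the informative components lock within tens of
    iterations while the noise subspace keeps rotating.  A fit that ends
    at ``max_iter`` is therefore returned with a ``ConvergenceWarning``
    rather than discarded; restarts with incremented seeds are used when
    a fit produces invalid (non-finite) output, and ``strict=True``
    upgrades residual non-convergence to :class:`DecompositionError`.

    Component sign is fixed so that the largest-|value| entry of each
    inverse-weight column is positive, making heat-maps and downstream
    matching deterministic under the ICA sign ambiguity.
    """
    if rec.stage != "filtered":
        raise ValueError("fit_ica expects a filtered recording")
    X = rec.samples.T  # (T, C)
    if X.shape[0] <= 10 * X.shape[1]:
        raise ValueError("too few time samples relative to channels")
    n_components = n_components or rec.n_channels
    stride = max(1, X.shape[0] // fit_samples)
    Xfit = X[::stride]

    converged = False
    last_n_iter = -1
    ica = None
    for attempt in range(restarts + 1):
        cand = FastICA(
            n_components=n_components,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            tol=tol,
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cand.fit(Xfit)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        last_n_iter = cand.n_iter_
        if np.all(np.isfinite(cand.components_)):
            ica = cand
            break
    if ica is None:
        raise DecompositionError(
            f"FastICA produced invalid unmixing matrices in {restarts + 1} attempts "
            f"(last run used {last_n_iter} iterations)"
        )
    if not converged:
        msg = (
            f"FastICA stopped at max_iter={max_iter} without reaching tol={tol} "
            "(expected when a noise subspace is present); result retained"
        )
        if strict:
            raise DecompositionError(msg)
        warnings.warn(msg, ConvergenceWarning, stacklevel=2)

    W = ica.components_.copy()  # (K, C)
    mean = ica.mean_
    S = (X - mean) @ W.T  # (T, K), full length
    # renormalize to unit variance over the full recording
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    S /= sd
    W /= sd[:, None]
    A = np.linalg.pinv(W)  # (C, K)
    S = S.T  # (K, T)

    # sign convention: dominant inverse-weight entry positive
    for k in range(S.shape[0]):
        j = np.argmax(np.abs(A[:, k]))
        if A[j, k] < 0:
            A[:, k] *= -1
            W[k, :] *= -1
            S[k, :] *= -1

    return ComponentSet(S, W, A, mean, rec.fs)


# ---------------------------------------------------------------------------
# spectral triage

def compute_psd(
    component: np.ndarray,
    fs: float,
    thresholds: TriageThresholds | None = None,
) -> SpectralProfile:
    """Welch PSD (1 s Hann segments, 50% overlap) with triage scores.

    1 s segments give 1 Hz bins, enough to resolve the harmonic spacing
    of powerline interference at typical sEMG rates.
    """
    th = thresholds or TriageThresholds()
    x = np.asarray(component, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of samples for a PSD")
    nperseg = int(fs)
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)

    total = np.trapezoid(p, f)
    lo, hi = th.band
    sel = (f >= lo) & (f <= hi)
    band_fraction = float(np.trapezoid(p[sel], f[sel]) / total) if total > 0 else 0.0

    harmonic_score = float(_harmonic_peak_count(f, p, th))

    flo, fhi = th.slope_fit_band
    fit = (f >= flo) & (f <= fhi) & (p > 0)
    if fit.sum() >= 3:
        slope = float(np.polyfit(np.log10(f[fit]), np.log10(p[fit]), 1)[0])
    else:
        slope = 0.0
    return SpectralProfile(f, p, band_fraction, harmonic_score, slope)


def _harmonic_peak_count(f: np.ndarray, p: np.ndarray, th: TriageThresholds) -> int:
    """Largest number of baseline-exceeding peaks aligned on a common fundamental.

    Peaks are judged against a median-smoothed log-PSD baseline rather
    than against neighboring minima: narrow notches left by the comb
    filter dip *below* the baseline and must not make the plateau between
    them look like a harmonic series, while genuine periodic interference
    produces lines standing above it.
    """
    from scipy.ndimage import median_filter  # noqa: PLC0415

    valid = f >= 10.0
    logp = 10.0 * np.log10(np.maximum(p[valid], np.max(p) * 1e-12))
    df = f[1] - f[0] if len(f) > 1 else 1.0
    size = max(3, int(round(15.0 / df)) | 1)  # ~15 Hz median window, odd
    baseline = median_filter(logp, size=size, mode="nearest")
    peaks, _ = sps.find_peaks(logp - baseline, height=th.harmonic_prominence_db)
    freqs = f[valid][peaks]
    if len(freqs) < 2:
        return len(freqs)
    best = 1
    for f0 in freqs:
        k = np.round(freqs / f0)
        aligned = (k >= 1) & (np.abs(freqs - k * f0) <= th.harmonic_tol_hz)
        best = max(best, int(aligned.sum()))
    return best


def classify_component(
    profile: SpectralProfile, thresholds: TriageThresholds | None = None
) -> tuple[str, dict]:
    """Apply the three sEMG acceptance criteria to one spectral profile."""
    th = thresholds or TriageThresholds()
    flags = {
        "band_ok": profile.band_fraction_25_300 >= th.min_band_fraction,
        "no_harmonics": profile.harmonic_score < th.harmonic_min_peaks,
        "no_one_over_f": profile.one_over_f_slope > th.min_slope,
    }
    label = "semg" if all(flags.values()) else "noise"
    return label, flags


def classify_components(
    cs: ComponentSet, thresholds: TriageThresholds | None = None
) -> ComponentSet:
    """Label every component of a decomposition as sEMG or noise."""
    th = thresholds or TriageThresholds()
    for k in range(cs.n_components):
        profile = compute_psd(cs.sources[k], cs.fs, th)
        label, flags = classify_component(profile, th)
        cs.labels[k] = label
        cs.flags[k] = flags
    return cs


# ---------------------------------------------------------------------------
# ground-truth evaluation helpers

def match_components_to_sources(
    cs: ComponentSet, true_sources: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one pairing of components to known sources by |correlation|.

    Returns ``(component_index_per_source, |corr| per source)`` from an
    optimal assignment over all pairings (Hungarian algorithm), which
    makes the evaluation invariant to ICA's permutation and sign
    ambiguities.
    """
    K = true_sources.shape[0]
    n = min(cs.sources.shape[1], true_sources.shape[1])
    Sc = cs.sources[:, :n] - cs.sources[:, :n].mean(axis=1, keepdims=True)
    St = true_sources[:, :n] - true_sources[:, :n].mean(axis=1, keepdims=True)
    Sc /= np.linalg.norm(Sc, axis=1, keepdims=True)
    St /= np.linalg.norm(St, axis=1, keepdims=True)
    corr = np.abs(St @ Sc.T)  # (K_true, K_est)
    rows, cols = optimize.linear_sum_assignment(-corr)
    match = np.empty(K, dtype=int)
    scores = np.empty(K)
    for r, c in zip(rows, cols):
        match[r] = c
        scores[r] = corr[r, c]
    return match, scores


def amari_index(A_est: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation/scale-invariant mismatch between mixing matrices, in [0, 1].

    Computed from the gain matrix P = pinv(A_est) A_true; 0 means the
    estimated columns span the true ones exactly up to permutation and
    scale.
    """
    P = np.abs(np.linalg.pinv(A_est) @ A_true)
    K = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("matched mixing matrices must have the same number of columns")
    if K < 2:
        return 0.0
    rows = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((rows + cols) / (2 * K * (K - 1)))
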