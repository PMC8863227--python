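"""Bidirectional cross-reconstruction between IC envelopes and AU tracks.

The quantitative comparison between modalities is ordinary multiple
linear regression with intercept:

    y_i = b0 + b1 x_i1 + ... + bp x_ip + e_i

fitted one dependent series at a time: an AU intensity track regressed on
all IC envelope tracks (AU <- ICs), or an IC envelope regressed on all AU
tracks (IC <- AUs).  Model quality is reported as R^2, the overall
F-statistic with (p, n-p-1) degrees of freedom, its p-value, and the
residual (error) variance SSR/(n-p-1).  Absolute slopes, row-normalized
to unit maximum, form the grey-level weight tables used to read off which
explanatory track dominates each reconstruction.

A smile segmenter is also provided: candidate windows from instruction
triggers (with a fixed 0.5 s margin) are kept when the segment RMS of the
ordering component exceeds the neutral-baseline RMS by the SNR threshold,
and returned sorted from biggest to smallest activation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .alignment import AlignedSession

__all__ = [
    "InsufficientDataError",
    "RegressionResult",
    "WeightTable",
    "SmileSegment",
    "fit_mlr",
    "reconstruct_au_from_ics",
    "reconstruct_ic_from_aus",
    "build_weight_table",
    "segment_smiles",
    "DEFAULT_TARGET_AUS",
]

#: Default AU subset for intra-session reconstruction reports: brow
#: lowerer, cheek raiser, lip corner puller, lips part, lip tightener and
#: nose wrinkler — the six AUs most engaged by the calibration
#: expressions.  A variance-ranked top-k alternative is available through
#: the pipeline configuration.
DEFAULT_TARGET_AUS: tuple[int, ...] = (4, 6, 12, 25, 23, 9)


class InsufficientDataError(ValueError):
    """Too few observations for the requested model."""


@dataclass
class RegressionResult:
    """One fitted MLR model and its quality metrics."""

    dependent_id: str
    explanatory_ids: list
    intercept: float
    slopes: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    f_statistic: float
    f_pvalue: float
    error_variance: float
    n_obs: int

    @property
    def p(self) -> int:
        return len(self.slopes)


@dataclass
class WeightTable:
    """Per-dependent normalized |slope| weights (rows sum to the dependents).

    Each nonzero row is scaled to unit maximum; in the grey-level
    rendering convention, white marks the most influential explanatory
    track for that dependent.
    """

    values: np.ndarray  # (n_dependents, n_explanatory)
    row_ids: list
    col_ids: list

    def to_dataframe(self):
        import pandas as pd  # noqa: PLC0415

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class SmileSegment:
    """One retained smile window with per-track activation summaries."""

    onset: float
    offset: float
    snr: float
    fbb_rms: dict[str, float] = field(default_factory=dict)
    au_means: dict[int, float] = field(default_factory=dict)


def fit_mlr(
    y: np.ndarray,
    X: np.ndarray,
    dependent_id: str = "y",
    explanatory_ids: list | None = None,
) -> RegressionResult:
    """Ordinary least squares with intercept, via statsmodels.

    Rank-deficient design matrices are handled by the pseudo-inverse (a
    warning is emitted).  A constant dependent has no variance to
    explain; by convention R^2 = 0 and F = 0 (p-value 1) in that case.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have different numbers of observations")
    if n <= p + 1:
        raise InsufficientDataError(f"need n > p+1 observations (n={n}, p={p})")
    if explanatory_ids is None:
        explanatory_ids = list(range(p))

    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        warnings.warn("rank-deficient design; coefficients from pseudo-inverse", stacklevel=2)

    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    res = model.fit()
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    if np.ptp(y) == 0.0:
        r2, f, fp = 0.0, 0.0, 1.0
    else:
        r2 = float(res.rsquared)
        f = float(res.fvalue)
        fp = float(res.f_pvalue)
        if not np.isfinite(f):
            f, fp = 0.0, 1.0
    return RegressionResult(
        dependent_id=dependent_id,
        explanatory_ids=list(explanatory_ids),
        intercept=float(res.params[0]),
        slopes=np.asarray(res.params[1:]),
        fitted=fitted,
        residuals=resid,
        r_squared=min(max(r2, 0.0), 1.0),
        f_statistic=f,
        f_pvalue=fp,
        error_variance=float(res.ssr / (n - p - 1)),
        n_obs=n,
    )


def reconstruct_au_from_ics(session: AlignedSession, au_id: int) -> RegressionResult:
    """Reconstruct one AU intensity track from all IC envelope tracks."""
    if au_id not in session.au_tracks:
        raise KeyError(f"AU{au_id} not present in session")
    ids, X = session.ic_matrix()
    if not ids:
        raise ValueError("session has no IC tracks")
    return fit_mlr(session.au_tracks[au_id], X, dependent_id=f"AU{au_id}", explanatory_ids=ids)


def reconstruct_ic_from_aus(session: AlignedSession, fbb_id: str) -> RegressionResult:
    """Reconstruct one IC envelope track from all AU tracks."""
    if fbb_id not in session.ic_tracks:
        raise KeyError(f"IC {fbb_id!r} not present in session")
    ids, X = session.au_matrix()
    return fit_mlr(session.ic_tracks[fbb_id], X, dependent_id=str(fbb_id), explanatory_ids=ids)


def build_weight_table(results: list[RegressionResult]) -> WeightTable:
    """Row-normalized |slope| matrix across several reconstructions."""
    if not results:
        raise ValueError("need at least one regression result")
    cols = results[0].explanatory_ids
    for r in results[1:]:
        if r.explanatory_ids != cols:
            raise ValueError("results do not share explanatory ids")
    M = np.abs(np.stack([r.slopes for r in results]))
    for i in range(M.shape[0]):
        m = M[i].max()
        if m > 0:
            M[i] /= m
        else:
            warnings.warn(f"all-zero weight row for {results[i].dependent_id}", stacklevel=2)
    return WeightTable(M, [r.dependent_id for r in results], list(cols))


def segment_smiles(
    session: AlignedSession,
    order_by: str,
    snr_threshold: float = 1.25,
    margin: float = 0.5,
) -> list[SmileSegment]:
    """Segment smile events and order them by muscle activation.

    One candidate window per trigger (onset - margin to offset + margin);
    the baseline is the RMS of the ordering track over all frames outside
    every candidate window (neutral periods).  Windows whose segment RMS
    exceeds ``snr_threshold`` times the baseline are kept and returned
    sorted by descending segment RMS of the ordering track.
    """
    if session.triggers is None or len(session.triggers) == 0:
        return []
    if order_by not in session.ic_tracks:
        raise KeyError(f"ordering track {order_by!r} not present")
    fr = session.frame_rate
    n = session.n_frames
    ref = session.ic_tracks[order_by]

    windows = []
    inside = np.zeros(n, dtype=bool)
    for e in session.triggers:
        a = max(int(np.floor((e.onset - margin) * fr)), 0)
        b = min(int(np.ceil((e.offset + margin) * fr)), n)
        if b > a:
            windows.append((e, a, b))
            inside[a:b] = True

    baseline_frames = ref[~inside]
    if baseline_frames.size == 0:
        raise ValueError("no neutral frames left to estimate the SNR baseline")
    baseline = float(np.sqrt(np.mean(baseline_frames**2)))

    segments = []
    for e, a, b in windows:
        seg_rms = float(np.sqrt(np.mean(ref[a:b] ** 2)))
        snr = seg_rms / baseline if baseline > 0 else np.inf
        if snr > snr_threshold:
            segments.append(
                (
                    seg_rms,
                    SmileSegment(
                        onset=e.onset,
                        offset=e.offset,
                        snr=snr,
                        fbb_rms={
                            k: float(np.sqrt(np.mean(v[a:b] ** 2)))
                            for k, v in session.ic_tracks.items()
                        },
                        au_means={
                            au: float(np.mean(v[a:b])) for au, v in session.au_tracks.items()
                        },
                    ),
                )
            )
    segments.sort(key=lambda t: -t[0])
    return [s for _, s in segments]
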