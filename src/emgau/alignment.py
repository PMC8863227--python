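"""Envelope extraction and sEMG/video co-registration.

Independent-component source signals live at the sEMG rate (3000 samples/s);
action-unit tracks at video rate (30 frames/s).  The bridge is a moving
root-mean-square envelope (800-sample window at the native rate, i.e.
~267 ms) followed by integer-factor block-mean decimation.  The RMS is
computed *before* decimation: an 800-sample window applied at 30 frames/s
would span 26.7 s, far beyond expression dynamics, so the native-rate
ordering is the default (the alternative is available via ``rms_after``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AUTrackSet, TriggerList

__all__ = [
    "AlignmentError",
    "AlignedSession",
    "rms_envelope",
    "resample_track",
    "align_session",
    "select_active_aus",
]


class AlignmentError(ValueError):
    """Modalities cannot be co-registered."""


@dataclass
class AlignedSession:
    """Co-sampled IC envelope tracks and AU tracks at video rate.

    Columns of this structure are the observations fed to the regression
    stage: an AU intensity series regressed on all IC envelopes, or vice
    versa.
    """

    frame_rate: float
    ic_tracks: dict[str, np.ndarray]
    au_tracks: dict[int, np.ndarray]
    triggers: TriggerList | None = None
    n_frames: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.ic_tracks.values()} | {
            len(v) for v in self.au_tracks.values()
        }
        if len(lengths) > 1:
            raise AlignmentError(f"track lengths differ: {sorted(lengths)}")
        self.n_frames = lengths.pop() if lengths else 0

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def ic_matrix(self) -> tuple[list[str], np.ndarray]:
        """IC envelope tracks as (ids, n_frames x n_ics matrix), id-sorted."""
        ids = sorted(self.ic_tracks)
        if not ids:
            return ids, np.empty((self.n_frames, 0))
        return ids, np.column_stack([self.ic_tracks[i] for i in ids])

    def au_matrix(self) -> tuple[list[int], np.ndarray]:
        ids = sorted(self.au_tracks)
        return ids, np.column_stack([self.au_tracks[i] for i in ids])


def rms_envelope(signal: np.ndarray, window: int = 800) -> np.ndarray:
    """Centered moving-window RMS, same length as the input.

    Edge windows are truncated to the available samples (no padding), so
    the envelope never contains fabricated values.  Computed with a
    cumulative sum of squares; O(n) regardless of window size.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    if window > n:
        raise ValueError(f"window ({window}) exceeds signal length ({n})")
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)
    lo = np.maximum(i - window // 2, 0)
    hi = np.minimum(i - window // 2 + window, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def resample_track(track: np.ndarray, fs_in: float, fs_out: float = 30.0) -> np.ndarray:
    """Integer-factor block-mean decimation from ``fs_in`` to ``fs_out``.

    Each output frame is the mean of the ``fs_in/fs_out`` input samples it
    covers; a trailing partial block is discarded, so the output length is
    ``floor(len * fs_out / fs_in)``.
    """
    if fs_in < fs_out:
        raise ValueError("fs_in must be >= fs_out")
    ratio_f = fs_in / fs_out
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer (got {ratio_f})")
    x = np.asarray(track, dtype=float)
    n_out = x.size // ratio
    return x[: n_out * ratio].reshape(n_out, ratio).mean(axis=1)


def align_session(
    cs,
    aus: AUTrackSet,
    triggers: TriggerList | None = None,
    offset: float = 0.0,
    window: int = 800,
    rms_after: bool = False,
) -> AlignedSession:
    """Build an :class:`AlignedSession` from classified components and AU tracks.

    Only components labeled ``semg`` enter; each is converted to a
    video-rate RMS envelope, shifted by ``offset`` seconds relative to the
    AU tracks, and both modalities are truncated to their common span.
    Frames where any AU track is NaN (long tracking-failure runs) are
    dropped pairwise from both modalities.

    Parameters
    ----------
    cs : ComponentSet
        Output of the ICA stage, already classified.
    offset : float
        Positive values advance the sEMG clock relative to video, i.e. the
        IC tracks are shifted ``offset * frame_rate`` frames earlier.
    rms_after : bool
        Apply the RMS window after decimation instead of before (the
        window is then in frames).  Off by default; see module docstring.
    """
    fr = aus.frame_rate
    semg = [k for k, lab in enumerate(cs.labels) if lab == "semg"]
    ic_tracks: dict[str, np.ndarray] = {}
    for k in semg:
        name = cs.fbb_ids[k] if cs.fbb_ids[k] is not None else f"IC{k:02d}"
        sig = cs.sources[k]
        if rms_after:
            env = rms_envelope(resample_track(np.abs(sig), cs.fs, fr), window)
        else:
            env = resample_track(rms_envelope(sig, window), cs.fs, fr)
        ic_tracks[str(name)] = env

    shift = int(round(offset * fr))
    if shift > 0:
        ic_tracks = {k: v[shift:] for k, v in ic_tracks.items()}
    elif shift < 0:
        au_sl = slice(-shift, None)
        aus = AUTrackSet(fr, {a: t[au_sl] for a, t in aus.tracks.items()})

    n_ic = min((len(v) for v in ic_tracks.values()), default=None)
    n = aus.n_frames if n_ic is None else min(n_ic, aus.n_frames)
    if n == 0:
        raise AlignmentError("sEMG and AU spans do not overlap")

    ic_tracks = {k: v[:n] for k, v in ic_tracks.items()}
    au_tracks = {a: t[:n].copy() for a, t in aus.tracks.items()}

    # pairwise-drop frames with missing AU data
    if au_tracks:
        good = np.all(np.column_stack([np.isfinite(t) for t in au_tracks.values()]), axis=1)
        if not good.all():
            ic_tracks = {k: v[good] for k, v in ic_tracks.items()}
            au_tracks = {a: t[good] for a, t in au_tracks.items()}

    return AlignedSession(fr, ic_tracks, au_tracks, triggers)


def select_active_aus(aus: AUTrackSet, frac: float = 0.05, min_dur: float = 1.0) -> tuple[int, ...]:
    """AUs whose intensity exceeds ``frac`` of full scale continuously for ``min_dur``.

    The threshold is ``frac * 5`` on the 0-5 intensity scale (0.25 at the
    default 5%); an AU qualifies if a run of at least
    ``min_dur * frame_rate`` consecutive frames stays above it.
    """
    thr = frac * 5.0
    need = int(round(min_dur * aus.frame_rate))
    keep = []
    for au in aus.au_ids:
        v = aus.tracks[au]
        above = np.isfinite(v) & (v > thr)
        # longest run of True
        run = best = 0
        for a in above:
            run = run + 1 if a else 0
            best = max(best, run)
            if best >= need:
                break
        if need > 0 and best >= need:
            keep.append(au)
    return tuple(keep)
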