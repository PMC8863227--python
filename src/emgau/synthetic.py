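"""Synthetic paired sEMG / action-unit sessions with known ground truth.

The generator emulates the calibration protocol used for facial-expression
mapping experiments: six instructed expressions (big smile, wrinkle the
nose, close the eyes, contract the eyebrows, press the lips, small smile),
each shown for 3 s followed by a 3 s neutral gap and repeated 3 times
consecutively, recorded by a 16-electrode array at 3000 samples/s together
with 30 frames/s video-derived AU intensity tracks.

Muscle sources are band-limited noise bursts (25-300 Hz carrier) gated by
the protocol with 100 ms raised-cosine ramps, mixed onto the array by a
spatially decaying Gaussian gain profile
``A[c, k] = exp(-||pos_c - center_k||^2 / (2 sigma_s^2))``.  Interference
mimics the classes the component triage must reject: a 50 Hz powerline
comb (shared waveform, near-unit per-channel gains), low-rank 1/f noise
(spectrally shaped white noise, exponent alpha), and white sensor noise.

AU tracks are noisy linear superpositions of the sources' RMS envelopes:
``AU = clip_0^5(G . envelopes + noise)``.  The default weight matrix G
plants 10-30% crosstalk from the Zygomaticus-like big-smile source into
eye-region AUs — the confound structure that the regression stage is
designed to expose.  The envelopes use the same ``rms_envelope`` operation
as the analysis pipeline, so a noiseless session is an exact linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .alignment import resample_track, rms_envelope
from .io import (
    STANDARD_AU_IDS,
    AUTrackSet,
    ElectrodeLayout,
    Recording,
    TriggerEvent,
    TriggerList,
    default_layout,
)

__all__ = [
    "EXPRESSIONS",
    "SourceSpec",
    "NoiseSpec",
    "GroundTruth",
    "SessionConfig",
    "make_calibration_protocol",
    "make_smile_protocol",
    "synthesize_semg",
    "synthesize_aus",
    "generate_session",
    "default_session_config",
    "crosstalk_session_config",
    "smile_session_config",
]

#: The six instructed calibration expressions, in presentation order.
EXPRESSIONS: tuple[str, ...] = (
    "big smile",
    "wrinkle the nose",
    "close the eyes",
    "contract the eyebrows",
    "press the lips",
    "small smile",
)

#: Face-frame centers of the muscle source emulating each expression.
#: big/small smile -> cheek (Zygomaticus-like), nose -> upper cheek,
#: eyes -> periocular, eyebrows -> brow (Corrugator-like), lips -> mouth.
SOURCE_CENTERS: dict[str, tuple[float, float]] = {
    "big smile": (0.55, 0.35),
    "wrinkle the nose": (0.30, 0.50),
    "close the eyes": (0.62, 0.62),
    "contract the eyebrows": (0.52, 0.82),
    "press the lips": (0.42, 0.10),
    "small smile": (0.68, 0.28),
}


@dataclass
class SourceSpec:
    """One muscle(-segment) source: where it sits and when it fires."""

    source_id: str
    center: tuple[float, float]
    spread: float = 0.15  # sigma_s, layout units
    events: list[tuple[float, float, float]] = field(default_factory=list)  # (onset, dur, amp)
    band: tuple[float, float] = (25.0, 300.0)

    def __post_init__(self) -> None:
        if any(a < 0 for _, _, a in self.events):
            raise ValueError("event amplitudes must be >= 0")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError(f"invalid carrier band {self.band}")


@dataclass
class NoiseSpec:
    """Interference model: powerline comb, low-rank 1/f noise, white noise."""

    powerline_freq: float = 50.0
    powerline_harmonics: tuple[float, ...] = (0.2, 0.08, 0.03, 0.01)  # amplitude per harmonic
    one_over_f_alpha: float = 1.0
    one_over_f_amp: float = 0.15
    n_one_over_f: int = 2
    white_sigma: float = 0.05

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.powerline_harmonics) or self.one_over_f_amp < 0 or self.white_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    sources: np.ndarray  # (K, T) true source signals
    mixing: np.ndarray  # (C, K) true mixing matrix A_true
    au_weights: np.ndarray | None  # (n_au, K) true AU weight matrix G
    au_noise: float
    triggers: TriggerList
    source_specs: list[SourceSpec]
    fs: float
    au_ids: tuple[int, ...] = ()

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]

    def source_envelopes(self, window: int = 800, frame_rate: float = 30.0) -> np.ndarray:
        """Video-rate RMS envelopes of the true sources, (K, n_frames)."""
        return np.stack(
            [resample_track(rms_envelope(s, window), self.fs, frame_rate) for s in self.sources]
        )


# ---------------------------------------------------------------------------
# protocols

def make_calibration_protocol(n_reps: int = 3, seed: int | None = None) -> TriggerList:
    """The instructed-expression calibration protocol.

    Each of the six expressions is presented for 3 s followed by a 3 s
    neutral gap, ``n_reps`` times consecutively, in fixed presentation
    order.  ``seed`` is accepted for interface symmetry with the other
    generators; the protocol itself is deterministic.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    events = []
    t = 0.0
    for expr in EXPRESSIONS:
        for _ in range(n_reps):
            events.append(TriggerEvent(expr, t, t + 3.0))
            t += 6.0
    return TriggerList(events)


def make_smile_protocol(
    n_smiles: int = 8, on: float = 2.0, gap: float = 4.0, lead_in: float = 4.0
) -> TriggerList:
    """Spontaneous-smile protocol: ``n_smiles`` smile windows separated by rest."""
    events = []
    t = lead_in
    for i in range(n_smiles):
        events.append(TriggerEvent(f"smile {i + 1}", t, t + on))
        t += on + gap
    return TriggerList(events)


# ---------------------------------------------------------------------------
# signal primitives

def _raised_cosine_gate(n: int, fs: float, events, ramp: float = 0.1) -> np.ndarray:
    """Amplitude gate: 0 at rest, event amplitude during bursts, 100 ms cosine ramps."""
    t = np.arange(n) / fs
    gate = np.zeros(n)
    for onset, dur, amp in events:
        rise = np.clip((t - onset) / ramp, 0.0, 1.0)
        fall = np.clip((onset + dur - t) / ramp, 0.0, 1.0)
        w = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
        gate = np.maximum(gate, amp * w)
    return gate


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited by a 4th-order Butterworth."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x * x))


def _one_over_f_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-RMS noise with power spectrum ~ f^-alpha (spectral shaping)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity; DC is zeroed below
    spec *= f ** (-alpha / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x * x))


# ---------------------------------------------------------------------------
# generators

def synthesize_semg(
    sources: list[SourceSpec],
    layout: ElectrodeLayout | None = None,
    noise: NoiseSpec | None = None,
    fs: float = 3000.0,
    duration: float | None = None,
    seed: int = 0,
    triggers: TriggerList | None = None,
) -> tuple[Recording, GroundTruth]:
    """Mix gated band-limited sources onto the electrode array and add noise."""
    if not sources:
        raise ValueError("at least one source required")
    layout = layout or default_layout()
    noise = noise or NoiseSpec()
    for spec in sources:
        if not (0 <= spec.center[0] <= 1 and 0 <= spec.center[1] <= 1):
            raise ValueError(f"source {spec.source_id!r} center outside [0,1]^2")
    end = max((on + dur for s in sources for on, dur, _ in s.events), default=0.0)
    if duration is None:
        duration = end + 3.0
    elif duration < end:
        raise ValueError("duration does not cover all activation events")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    S = np.empty((len(sources), n))
    for k, spec in enumerate(sources):
        carrier = _band_limited_noise(rng, n, fs, spec.band)
        S[k] = _raised_cosine_gate(n, fs, spec.events) * carrier

    # spatially decaying mixing
    A = np.empty((len(layout), len(sources)))
    for k, spec in enumerate(sources):
        d2 = np.sum((layout.coords - np.asarray(spec.center)) ** 2, axis=1)
        A[:, k] = np.exp(-d2 / (2.0 * spec.spread**2))

    X = A @ S

    t = np.arange(n) / fs
    if any(a > 0 for a in noise.powerline_harmonics):
        wave = np.zeros(n)
        for h, amp in enumerate(noise.powerline_harmonics, start=1):
            f = noise.powerline_freq * h
            if f < fs / 2 and amp > 0:
                wave += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        gains = rng.uniform(0.8, 1.2, size=len(layout))
        X += gains[:, None] * wave[None, :]

    if noise.one_over_f_amp > 0 and noise.n_one_over_f > 0:
        drift = np.stack(
            [_one_over_f_noise(rng, n, noise.one_over_f_alpha) for _ in range(noise.n_one_over_f)]
        )
        mix = rng.normal(0.0, 1.0, size=(len(layout), noise.n_one_over_f))
        X += noise.one_over_f_amp * (mix @ drift)

    if noise.white_sigma > 0:
        X += noise.white_sigma * rng.standard_normal(X.shape)

    rec = Recording(X, fs, layout.channel_ids.copy(), layout, stage="raw")
    truth = GroundTruth(
        sources=S,
        mixing=A,
        au_weights=None,
        au_noise=0.0,
        triggers=triggers if triggers is not None else TriggerList([]),
        source_specs=list(sources),
        fs=fs,
    )
    return rec, truth


def synthesize_aus(
    truth: GroundTruth,
    G: np.ndarray,
    sigma_au: float = 0.05,
    frame_rate: float = 30.0,
    seed: int = 0,
    au_ids: tuple[int, ...] | None = None,
    window: int = 800,
) -> AUTrackSet:
    """AU tracks as noisy superpositions of the true sources' RMS envelopes."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] != truth.n_sources:
        raise ValueError(
            f"G must have one column per source ({truth.n_sources}); got shape {G.shape}"
        )
    if au_ids is None:
        au_ids = STANDARD_AU_IDS[: G.shape[0]]
    if len(au_ids) != G.shape[0]:
        raise ValueError("one AU id per row of G required")
    env = truth.source_envelopes(window=window, frame_rate=frame_rate)
    rng = np.random.default_rng(seed)
    tracks_mat = G @ env
    if sigma_au > 0:
        tracks_mat = tracks_mat + sigma_au * rng.standard_normal(tracks_mat.shape)
    tracks_mat = np.clip(tracks_mat, 0.0, 5.0)
    truth.au_weights = G
    truth.au_noise = sigma_au
    truth.au_ids = tuple(au_ids)
    return AUTrackSet(frame_rate, {au: tracks_mat[i] for i, au in enumerate(au_ids)})


# ---------------------------------------------------------------------------
# session configuration

@dataclass
class SessionConfig:
    """Full description of a synthetic paired session."""

    sources: list[SourceSpec]
    triggers: TriggerList
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    G: np.ndarray | None = None  # (n_au, n_sources); rows follow au_ids
    au_ids: tuple[int, ...] = STANDARD_AU_IDS
    sigma_au: float = 0.05
    fs: float = 3000.0
    frame_rate: float = 30.0
    duration: float | None = None
    layout: ElectrodeLayout = field(default_factory=default_layout)
    rms_window: int = 800


def _calibration_sources(triggers: TriggerList, spread: float = 0.15, amplitude: float = 1.0):
    sources = []
    for expr in EXPRESSIONS:
        events = [(e.onset, e.offset - e.onset, amplitude) for e in triggers if e.label == expr]
        sources.append(SourceSpec(expr, SOURCE_CENTERS[expr], spread, events))
    return sources


def _default_G(au_ids: tuple[int, ...] = STANDARD_AU_IDS) -> np.ndarray:
    """Default AU weight matrix over the six calibration sources.

    Rows follow ``au_ids``; columns follow :data:`EXPRESSIONS` order
    (big smile, nose, eyes, brows, lips, small smile).  Main weights put
    each AU on its anatomically plausible driver; eye-region AUs (AU6,
    AU7) additionally carry ~20% crosstalk from the big-smile
    (Zygomaticus-like) source.
    """
    w: dict[int, list[float]] = {au: [0.0] * 6 for au in au_ids}
    w[12] = [2.5, 0.0, 0.0, 0.0, 0.0, 1.5]  # lip corner puller <- smiles
    w[25] = [1.5, 0.0, 0.0, 0.0, 0.0, 0.8]  # lips part
    w[6] = [0.5, 0.0, 1.5, 0.0, 0.0, 0.3]  # cheek raiser: eye source + smile crosstalk
    w[7] = [0.4, 0.0, 1.2, 0.0, 0.0, 0.0]  # lid tightener: eye source + smile crosstalk
    w[45] = [0.0, 0.0, 2.5, 0.0, 0.0, 0.0]  # blink <- eye closure
    w[5] = [0.0, 0.0, 0.6, 0.0, 0.0, 0.0]
    w[4] = [0.0, 0.0, 0.0, 2.5, 0.0, 0.0]  # brow lowerer
    w[1] = [0.0, 0.0, 0.0, 0.8, 0.0, 0.0]
    w[2] = [0.0, 0.0, 0.0, 0.6, 0.0, 0.0]
    w[9] = [0.0, 2.5, 0.0, 0.0, 0.0, 0.0]  # nose wrinkler
    w[10] = [0.0, 1.2, 0.0, 0.0, 0.0, 0.0]
    w[23] = [0.0, 0.0, 0.0, 0.0, 2.5, 0.0]  # lip tightener
    w[14] = [0.0, 0.0, 0.0, 0.0, 0.8, 0.6]  # dimpler
    w[17] = [0.0, 0.0, 0.0, 0.0, 0.9, 0.0]
    w[15] = [0.0, 0.3, 0.0, 0.0, 0.4, 0.0]
    w[20] = [0.3, 0.0, 0.0, 0.0, 0.5, 0.0]
    w[26] = [0.6, 0.0, 0.0, 0.0, 0.0, 0.3]
    return np.array([w[au] for au in au_ids])


def default_session_config(n_reps: int = 3, sigma_au: float = 0.05) -> SessionConfig:
    """The default calibration session: 6 sources, 16 channels, 17 AU tracks."""
    triggers = make_calibration_protocol(n_reps)
    return SessionConfig(
        sources=_calibration_sources(triggers),
        triggers=triggers,
        G=_default_G(),
        sigma_au=sigma_au,
    )


def crosstalk_session_config(n_reps: int = 3, crosstalk: float = 0.5) -> SessionConfig:
    """Calibration session where the big-smile source has no dedicated AU.

    The Zygomaticus-like source appears in the AU tracks only through
    its crosstalk into the eye-region AUs (AU6/AU7) — the scenario in
    which cheek activity masquerades as periocular activity in
    video-based coding.
    """
    cfg = default_session_config()
    G = _default_G(cfg.au_ids).copy()
    idx = {au: i for i, au in enumerate(cfg.au_ids)}
    G[:, 0] = 0.0  # remove every direct readout of the big-smile source
    # a single crosstalk path keeps the planted confound identifiable:
    # cheek activity reaches the AU tracks only through the "cheek raiser"
    G[idx[6], 0] = crosstalk
    cfg.G = G
    return cfg


def smile_session_config(
    n_smiles: int = 8, amp_max: float = 1.0, amp_min: float = 0.3, sigma_au: float = 0.05
) -> SessionConfig:
    """Spontaneous-smile session: smile bursts with strictly decreasing amplitude.

    The Zygomaticus-like cheek source fires in every smile window with
    amplitudes falling linearly from ``amp_max`` to ``amp_min``; the
    periocular source co-fires at half amplitude on every other smile
    (Duchenne-like), so per-smile muscle profiles differ while the AU
    profiles stay similar.
    """
    triggers = make_smile_protocol(n_smiles)
    amps = np.linspace(amp_max, amp_min, n_smiles)
    cheek_events = [
        (e.onset, e.offset - e.onset, float(a)) for e, a in zip(triggers, amps)
    ]
    eye_events = [
        (e.onset, e.offset - e.onset, 0.5 * float(a))
        for i, (e, a) in enumerate(zip(triggers, amps))
        if i % 2 == 0
    ]
    sources = [
        SourceSpec("big smile", SOURCE_CENTERS["big smile"], 0.15, cheek_events),
        SourceSpec("close the eyes", SOURCE_CENTERS["close the eyes"], 0.15, eye_events),
    ]
    au_ids = (6, 12)
    G = np.array([[0.5, 1.5], [2.5, 0.0]])  # AU6 <- eye + smile crosstalk; AU12 <- smile
    return SessionConfig(
        sources=sources, triggers=triggers, G=G, au_ids=au_ids, sigma_au=sigma_au
    )


def generate_session(
    config: SessionConfig | None = None, seed: int = 0
) -> tuple[Recording, AUTrackSet, GroundTruth]:
    """Generate one paired session; deterministic for a fixed seed."""
    config = config if config is not None else default_session_config()
    ss = np.random.SeedSequence(seed)
    semg_seed, au_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    duration = config.duration
    if duration is None:
        duration = config.triggers.span + 3.0
    rec, truth = synthesize_semg(
        config.sources,
        config.layout,
        config.noise,
        fs=config.fs,
        duration=duration,
        seed=semg_seed,
        triggers=config.triggers,
    )
    G = config.G if config.G is not None else _default_G(config.au_ids)
    aus = synthesize_aus(
        truth,
        G,
        sigma_au=config.sigma_au,
        frame_rate=config.frame_rate,
        seed=au_seed,
        au_ids=config.au_ids,
        window=config.rms_window,
    )
    return rec, aus, truth
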