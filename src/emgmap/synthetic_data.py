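"""Protocol-structured synthetic sEMG cohorts.

Baseline activity on every channel is zero-mean Gaussian noise shaped to a
classical two-pole EMG-like target spectrum

    P(f)  proportional to  f_high^4 * f^2 / ((f^2 + f_low^2) (f^2 + f_high^2)^2).

During a compression, channels ipsilateral to the compressed breast whose
muscle has gain > 1 are (a) scaled by a participant-specific amplitude gain
and (b) mixed with a narrowband low-frequency component (default centered at
85 Hz, 10 Hz wide) replacing a ``spectral_mix`` fraction of the power.  The
admixture moves spectral mass downward and concentrates it, which decreases
meanFreq, medianFreq, DP and SpecDef exactly as activation should; a pure
amplitude gain alone would leave every frequency-domain metric unchanged.

Between-participant variability is a lognormal multiplier (unit mean) on
the gain *excess* g - 1, so that unactivated channels (g = 1) stay exactly
at baseline and a null cohort is exactly null.

Randomness is hierarchical: one root seed, per-participant child streams by
index, then per-segment substreams, so participant k's data does not depend
on the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session_io import (
    ALL_CHANNELS,
    ChannelId,
    Cohort,
    Muscle,
    Segment,
    SegmentLabel,
    Session,
    segment_role,
)

__all__ = [
    "SpectralShape",
    "ActivationMap",
    "SimConfig",
    "default_activation_map",
    "shaped_noise",
    "simulate_session",
    "simulate_cohort",
    "scaled_down_config",
]


@dataclass(frozen=True)
class SpectralShape:
    f_low: float = 60.0
    f_high: float = 120.0

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise ValueError("need 0 < f_low < f_high")

    def density(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=np.float64)
        f2 = np.square(f)
        return (
            self.f_high**4
            * f2
            / ((f2 + self.f_low**2) * np.square(f2 + self.f_high**2))
        )


_DEFAULT_GAINS: dict[Muscle, float] = {
    Muscle.DELTOID: 4.0,
    Muscle.STERNOCLEIDOMASTOID: 1.8,
    Muscle.TRAPEZIUS_UPPER: 1.9,
    Muscle.INFRASPINATUS: 2.0,
    Muscle.TERES_MAJOR: 1.6,
    Muscle.SERRATUS_ANTERIOR: 1.0,
    Muscle.EXTERNAL_OBLIQUE: 1.0,
}


@dataclass(frozen=True)
class ActivationMap:
    """Ipsilateral amplitude gains per muscle (optionally per view) plus the
    narrowband spectral admixture applied to activated channels.

    Contralateral channels always stay at gain 1."""

    # 85 Hz sits in the window where the admixture lowers the spectral-moment
    # ratio as well as meanFreq/medianFreq/DP; centers below ~80 Hz raise it
    # for the default baseline shape.
    gain: dict = field(default_factory=lambda: dict(_DEFAULT_GAINS))
    spectral_mix: float = 0.3
    nb_center_hz: float = 85.0
    nb_bw_hz: float = 10.0

    def __post_init__(self):
        if not (0 <= self.spectral_mix < 1):
            raise ValueError("spectral_mix must be in [0, 1)")
        for key, g in self.gain.items():
            if g < 1:
                raise ValueError(f"gain for {key} must be >= 1")

    def gain_for(self, muscle: Muscle, view: str) -> float:
        if (muscle, view) in self.gain:
            return float(self.gain[(muscle, view)])
        return float(self.gain.get(muscle, 1.0))


def default_activation_map(**overrides) -> ActivationMap:
    return ActivationMap(**overrides)


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 25
    fs: float = 1925.925
    baseline_sd_mv: float = 0.02
    between_participant_cv: float = 0.3
    seed: int = 0
    control_s: float = 120.0
    compression_s: float = 15.0
    shape: SpectralShape = field(default_factory=SpectralShape)
    channels: tuple[ChannelId, ...] = ALL_CHANNELS

    def __post_init__(self):
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        if self.baseline_sd_mv <= 0 or self.fs <= 0:
            raise ValueError("fs and baseline_sd_mv must be positive")
        if self.between_participant_cv < 0:
            raise ValueError("between_participant_cv must be >= 0")


def scaled_down_config(**overrides) -> SimConfig:
    """A desk-scale configuration (short segments, modest fs) for simulation
    studies; statistically equivalent to the full protocol, just noisier."""
    defaults = dict(fs=1200.0, control_s=10.0, compression_s=6.0)
    defaults.update(overrides)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# noise generators


def _shape_white(white: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """Filter white noise by an rfft-grid amplitude response, normalized so
    the output variance is exactly 1 in expectation."""
    n = white.shape[-1]
    spec = np.fft.rfft(white, axis=-1) * amp
    y = np.fft.irfft(spec, n=n, axis=-1)
    # expected variance of y for unit-variance white input
    sq = np.square(amp)
    if n % 2 == 0:
        var = (sq[0] + sq[-1] + 2.0 * np.sum(sq[1:-1])) / n
    else:
        var = (sq[0] + 2.0 * np.sum(sq[1:])) / n
    return y / np.sqrt(var)


def _broadband_amp(n: int, fs: float, shape: SpectralShape) -> np.ndarray:
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.sqrt(shape.density(f))
    amp[0] = 0.0
    return amp


def _narrowband_amp(n: int, fs: float, center: float, bw: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = bw / 2.355  # FWHM -> Gaussian sigma of the PSD bump
    amp = np.exp(-np.square(f - center) / (4.0 * sigma**2))
    amp[0] = 0.0
    return amp


def shaped_noise(
    n_samples: int,
    fs: float,
    shape: SpectralShape,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise with the EMG-like target spectrum."""
    if n_samples < 256:
        raise ValueError("need n_samples >= 256")
    white = rng.standard_normal(n_samples)
    return _shape_white(white, _broadband_amp(n_samples, fs, shape))


# ---------------------------------------------------------------------------
# session / cohort simulation


def _participant_multipliers(
    config: SimConfig, rng: np.random.Generator
) -> dict[Muscle, float]:
    cv = config.between_participant_cv
    if cv == 0:
        return {m: 1.0 for m in Muscle}
    sigma = float(np.sqrt(np.log1p(cv**2)))
    draws = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(Muscle))
    return dict(zip(Muscle, draws))


def simulate_session(
    participant_id: str,
    config: SimConfig,
    amap: ActivationMap | None = None,
    seed_seq: np.random.SeedSequence | int | None = None,
) -> Session:
    """One participant's 11-segment session under the activation map.

    Controls are pure baseline noise; during a compression, ipsilateral
    channels with map gain > 1 get the participant-specific gain
    ``1 + (g - 1) * L`` (L lognormal, unit mean) and the narrowband
    admixture; all other channels stay at baseline.
    """
    amap = amap or default_activation_map()
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    elif isinstance(seed_seq, int):
        seed_seq = np.random.SeedSequence(seed_seq)
    labels = list(SegmentLabel)
    streams = seed_seq.spawn(1 + len(labels))
    mult = _participant_multipliers(config, np.random.default_rng(streams[0]))

    channels = config.channels
    side_of = {"left": "L", "right": "R"}
    segments: dict[SegmentLabel, Segment] = {}
    for lab, stream in zip(labels, streams[1:]):
        role = segment_role(lab)
        dur = config.control_s if role.kind == "control" else config.compression_s
        n = int(round(dur * config.fs))
        rng = np.random.default_rng(stream)
        white = rng.standard_normal((len(channels), n))
        data = _shape_white(white, _broadband_amp(n, config.fs, config.shape))
        if role.kind == "compression":
            nb_amp = _narrowband_amp(n, config.fs, amap.nb_center_hz, amap.nb_bw_hz)
            for ci, ch in enumerate(channels):
                if side_of[ch.side.value] != role.side:
                    continue
                g = amap.gain_for(ch.muscle, role.view)
                if g <= 1.0:
                    continue
                g_p = 1.0 + (g - 1.0) * mult[ch.muscle]
                m = amap.spectral_mix
                if m > 0:
                    nb = _shape_white(rng.standard_normal(n), nb_amp)
                    mixed = np.sqrt(1.0 - m) * data[ci] + np.sqrt(m) * nb
                else:
                    mixed = data[ci]
                data[ci] = g_p * mixed
        segments[lab] = Segment(lab, config.baseline_sd_mv * data, config.fs)
    return Session(participant_id, segments, channels)


def simulate_cohort(
    config: SimConfig | None = None, amap: ActivationMap | None = None
) -> Cohort:
    """A reproducible cohort of ``n_participants`` independent sessions."""
    config = config or SimConfig()
    amap = amap or default_activation_map()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    sessions = [
        simulate_session(f"p{idx + 1:02d}", config, amap, child)
        for idx, child in enumerate(children)
    ]
    return Cohort(sessions)
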