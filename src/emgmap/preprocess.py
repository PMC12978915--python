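"""Edge trimming, bandpass filtering, RMS envelopes, and control-referenced
amplitude normalization.

The fixed pipeline order is trim -> bandpass -> normalize.  Normalization
divides every channel of every segment by the standard deviation of the RMS
envelope of that channel's *reference control* (C2 for the flat-paddle
family and for C1/C2 themselves, C3 for the curved-paddle family and C3),
which forces the stdRMS feature of each reference control to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .session_io import (
    ChannelId,
    Segment,
    SegmentLabel,
    Session,
    segment_role,
)

__all__ = [
    "PreprocessParams",
    "Envelope",
    "trim_edges",
    "bandpass",
    "rms_envelope",
    "normalize_session",
    "preprocess_session",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid preprocessing configuration for the given sampling rate."""


@dataclass
class PreprocessParams:
    trim_s: float = 1.5
    band_low_hz: float = 20.0
    band_high_hz: float = 500.0
    filter_order: int = 4
    env_window_s: float = 0.25
    env_overlap: float = 0.5

    def validate(self, fs: float) -> "PreprocessParams":
        if self.trim_s < 0:
            raise ConfigError("trim_s must be >= 0")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ConfigError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= fs / 2:
            raise ConfigError(
                f"band_high_hz={self.band_high_hz} must be below Nyquist {fs / 2}"
            )
        if not (0 <= self.env_overlap < 1):
            raise ConfigError("env_overlap must be in [0, 1)")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        return self


@dataclass
class Envelope:
    """RMS per sliding analysis window (nonnegative, same units as input)."""

    values: np.ndarray
    window_s: float
    overlap: float


def trim_edges(segment: Segment, params: PreprocessParams) -> Segment:
    """Drop the first and last ``trim_s`` seconds (floored to whole samples)."""
    n_trim = int(np.floor(params.trim_s * segment.fs))
    min_s = 2 * params.trim_s + 1.0
    if segment.duration_s <= min_s:
        raise ValueError(
            f"segment {segment.label.value}: duration {segment.duration_s:.2f} s "
            f"too short to trim (need > {min_s:.2f} s)"
        )
    if n_trim == 0:
        return segment.copy()
    return Segment(segment.label, segment.samples[:, n_trim:-n_trim].copy(), segment.fs)


from functools import lru_cache


@lru_cache(maxsize=32)
def _design_sos_cached(
    fs: float, low: float, high: float, order: int
) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _design_sos(fs: float, params: PreprocessParams) -> np.ndarray:
    return _design_sos_cached(
        fs, params.band_low_hz, params.band_high_hz, params.filter_order
    )


def bandpass(x: np.ndarray, fs: float, params: PreprocessParams) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward), DC removed.

    Accepts 1-D ``(n,)`` or 2-D ``(channels, n)`` input; filtering is along
    the last axis and the output has identical shape.
    """
    params.validate(fs)
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 3 * params.filter_order:
        raise ValueError(
            f"signal of length {x.shape[-1]} too short for order-"
            f"{params.filter_order} bandpass"
        )
    sos = _design_sos(fs, params)
    return sps.sosfiltfilt(sos, x, axis=-1)


def _window_geometry(n: int, fs: float, params: PreprocessParams) -> tuple[int, int]:
    w = int(round(params.env_window_s * fs))
    if w < 1:
        raise ConfigError("env_window_s shorter than one sample")
    if w > n:
        raise ValueError(f"envelope window ({w} samples) longer than signal ({n})")
    hop = max(1, int(round(w * (1.0 - params.env_overlap))))
    return w, hop


def rms_envelope(x: np.ndarray, fs: float, params: PreprocessParams) -> Envelope:
    """RMS over sliding windows of ``env_window_s`` advancing by
    ``window * (1 - env_overlap)`` samples; trailing partial windows dropped."""
    x = np.asarray(x, dtype=np.float64)
    w, hop = _window_geometry(x.shape[-1], fs, params)
    values = _rms_windows(x, w, hop)
    return Envelope(values, params.env_window_s, params.env_overlap)


def _rms_windows(x: np.ndarray, w: int, hop: int) -> np.ndarray:
    # works for 1-D and (channels, n); windows along last axis
    wins = sliding_window_view(x, w, axis=-1)[..., ::hop, :]
    return np.sqrt(np.mean(np.square(wins), axis=-1))


def normalize_session(
    session: Session, params: PreprocessParams
) -> tuple[Session, dict[tuple[ChannelId, SegmentLabel], float]]:
    """Divide each channel of each segment by its reference-control scale.

    The scale for channel *c* under reference control *R* is the sample
    standard deviation of *R*'s RMS envelope on channel *c*.  Returns the
    normalized session and the audit map ``(channel, reference) -> scale``.
    Segments are assumed trimmed and bandpassed already.
    """
    def norm_ref(lab: SegmentLabel) -> SegmentLabel:
        # C1 borrows C2's scale so the two rest states stay comparable
        if lab is SegmentLabel.C1:
            return SegmentLabel.C2
        return segment_role(lab).reference_control

    refs_needed = {norm_ref(lab) for lab in session.segments}
    scales: dict[tuple[ChannelId, SegmentLabel], float] = {}
    scale_vec: dict[SegmentLabel, np.ndarray] = {}
    for ref in sorted(refs_needed, key=lambda l: l.value):
        if ref not in session.segments:
            raise ValueError(f"reference control {ref.value} missing from session")
        env = rms_envelope(session.segments[ref].samples, session.fs, params)
        s = np.std(env.values, axis=-1, ddof=1)
        for ci, ch in enumerate(session.channel_order):
            if not s[ci] > 0:
                raise ValueError(
                    f"degenerate control channel: {ch} in {ref.value} has "
                    "zero-variance envelope"
                )
            scales[(ch, ref)] = float(s[ci])
        scale_vec[ref] = s
    out_segments = {}
    for lab, seg in session.segments.items():
        ref = norm_ref(lab)
        out_segments[lab] = Segment(
            lab, seg.samples / scale_vec[ref][:, None], seg.fs
        )
    return Session(session.participant_id, out_segments, session.channel_order), scales


def preprocess_session(
    session: Session, params: PreprocessParams | None = None
) -> tuple[Session, dict[tuple[ChannelId, SegmentLabel], float]]:
    """Full trim -> bandpass -> normalize pipeline on every segment."""
    params = params or PreprocessParams()
    params.validate(session.fs)
    filtered = {}
    for lab, seg in session.segments.items():
        trimmed = trim_edges(seg, params)
        filtered[lab] = Segment(
            lab, bandpass(trimmed.samples, session.fs, params), session.fs
        )
    staged = Session(session.participant_id, filtered, session.channel_order)
    return normalize_session(staged, params)
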