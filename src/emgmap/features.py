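"""The 10-metric feature bank: five time-domain metrics from the signal and
its RMS envelope, five frequency-domain metrics from a Welch power spectrum.

Time domain: meanRMS, stdRMS (mean / sample std of the RMS envelope), slope
sign changes (SSC) and zero crossings (ZC) per second, and waveform length
(WFL, total variation).  In assembled feature tables WFL is reported per
second: the protocol pairs 2-minute controls with 15-second compressions,
and a raw total variation would differ between them purely by duration,
which would masquerade as muscle activity in every paired contrast.

Frequency domain, computed on the 20-500 Hz band of the Welch PSD
(128-sample Blackman window, 50% overlap): mean frequency, median frequency
(linear interpolation of cumulative power at 0.5), normalized spectral
entropy in [0, 1], drop-in-power DP (fraction of in-band power at or above a
150 Hz split), and spectral deformation SpecDef = Omega2/Omega1 where
Omega_r = (M_r/M_0)^(1/r) with spectral moments M_r = sum f^r P(f).
SpecDef >= 1 for any spectrum with more than one active bin and equals 1
only for a single-line spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import PreprocessParams, rms_envelope
from .session_io import Session

__all__ = [
    "METRICS",
    "PsdParams",
    "Psd",
    "welch_psd",
    "time_domain_features",
    "freq_domain_features",
    "extract_features",
]

METRICS = (
    "meanRMS",
    "stdRMS",
    "SSC",
    "ZC",
    "WFL",
    "meanFreq",
    "medianFreq",
    "entropy",
    "DP",
    "SpecDef",
)


@dataclass
class PsdParams:
    nperseg: int = 128
    overlap: float = 0.5
    window: str = "blackman"
    band: tuple[float, float] = (20.0, 500.0)
    f_split_hz: float = 150.0

    def validate(self) -> "PsdParams":
        if self.nperseg < 8:
            raise ValueError("nperseg must be >= 8")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if not (0 <= self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 <= low < high")
        return self


@dataclass
class Psd:
    freqs_hz: np.ndarray
    power: np.ndarray
    params: PsdParams


def welch_psd(x: np.ndarray, fs: float, params: PsdParams | None = None) -> Psd:
    """Welch PSD with density scaling (integral over frequency ~ variance).

    Accepts 1-D or ``(channels, n)`` input; the power array then has the
    matching leading shape.
    """
    params = (params or PsdParams()).validate()
    x = np.asarray(x, dtype=np.float64)
    nper = params.nperseg
    if x.shape[-1] < nper:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than nperseg={nper}"
        )
    win = sps.get_window(params.window, nper)
    hop = nper - int(nper * params.overlap)
    segs = np.lib.stride_tricks.sliding_window_view(x, nper, axis=-1)[..., ::hop, :]
    spec = np.fft.rfft(segs * win, axis=-1)
    # one-sided density scaling: integral of power over frequency ~ variance
    scale = 1.0 / (fs * np.sum(win**2))
    power = np.mean(np.square(np.abs(spec)), axis=-2) * scale
    power[..., 1:] *= 2.0
    if nper % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return Psd(freqs, power, params)


# ---------------------------------------------------------------------------
# time domain


def _td_batch(
    x: np.ndarray,
    fs: float,
    pre_params: PreprocessParams,
    eps: float = 0.0,
    delta: float = 0.0,
    wfl_per_second: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorized time-domain metrics along the last axis of ``x``.

    ``wfl_per_second`` divides the waveform length by the segment duration,
    making it comparable between the long controls and short compressions;
    the raw operation reports the plain total variation.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples for time-domain features")
    duration = x.shape[-1] / fs
    env = rms_envelope(x, fs, pre_params).values
    mean_rms = np.mean(env, axis=-1)
    std_rms = np.std(env, axis=-1, ddof=1)

    d = np.diff(x, axis=-1)
    zc = np.sum(
        (x[..., :-1] * x[..., 1:] < 0) & (np.abs(d) >= eps), axis=-1
    ) / duration
    dl = x[..., 1:-1] - x[..., :-2]   # x_i - x_{i-1}
    dr = x[..., 1:-1] - x[..., 2:]    # x_i - x_{i+1}
    ssc = np.sum(
        (dl * dr > 0) & (np.maximum(np.abs(dl), np.abs(dr)) >= delta), axis=-1
    ) / duration
    wfl = np.sum(np.abs(d), axis=-1)
    if wfl_per_second:
        wfl = wfl / duration
    return {
        "meanRMS": mean_rms,
        "stdRMS": std_rms,
        "SSC": ssc,
        "ZC": zc,
        "WFL": wfl,
    }


def time_domain_features(
    x: np.ndarray,
    fs: float,
    pre_params: PreprocessParams | None = None,
    eps: float = 0.0,
    delta: float = 0.0,
) -> dict[str, float]:
    """The five time-domain metrics of a 1-D (normalized, filtered) signal.

    ``eps`` and ``delta`` are optional amplitude thresholds on the ZC and
    SSC counts; both default to pure sign logic.
    """
    vals = _td_batch(
        np.asarray(x, dtype=np.float64)[None, :],
        fs,
        pre_params or PreprocessParams(),
        eps=eps,
        delta=delta,
    )
    return {k: float(v[0]) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# frequency domain


def _fd_batch(psd: Psd) -> dict[str, np.ndarray]:
    params = psd.params
    low, high = params.band
    mask = (psd.freqs_hz >= low) & (psd.freqs_hz <= high)
    f = psd.freqs_hz[mask]
    if f.size < 1:
        raise ValueError("no PSD bins inside the analysis band")
    power = np.atleast_2d(psd.power)[..., mask]
    total = np.sum(power, axis=-1)
    if np.any(total <= 0):
        raise ValueError("silent segment: zero in-band power")
    p = power / total[..., None]

    mean_freq = p @ f

    cum = np.cumsum(p, axis=-1)
    median_freq = _interp_median(f, cum)

    k = f.size
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = (
        np.zeros(p.shape[:-1]) if k == 1 else -np.sum(plogp, axis=-1) / np.log(k)
    )

    dp = np.sum(np.where(f >= params.f_split_hz, p, 0.0), axis=-1)

    m1 = p @ f
    m2 = p @ np.square(f)
    spec_def = np.sqrt(m2) / m1
    return {
        "meanFreq": mean_freq,
        "medianFreq": median_freq,
        "entropy": entropy,
        "DP": dp,
        "SpecDef": spec_def,
    }


def _interp_median(f: np.ndarray, cum: np.ndarray) -> np.ndarray:
    """Frequency where cumulative normalized power crosses 0.5, linearly
    interpolated between bins; the first bin's mass is treated as a step."""
    idx = np.argmax(cum >= 0.5, axis=-1)
    out = np.empty(cum.shape[:-1])
    it = np.ndindex(*cum.shape[:-1])
    for ix in it:
        i = idx[ix]
        if i == 0:
            out[ix] = f[0]
            continue
        c_lo = cum[ix][i - 1]
        c_hi = cum[ix][i]
        frac = (0.5 - c_lo) / (c_hi - c_lo)
        out[ix] = f[i - 1] + frac * (f[i] - f[i - 1])
    return out


def freq_domain_features(psd: Psd) -> dict[str, float]:
    """The five frequency-domain metrics of a 1-D PSD restricted to band."""
    if np.atleast_2d(psd.power).shape[-1] < 2:
        raise ValueError("need at least 2 PSD bins")
    vals = _fd_batch(psd)
    return {k: float(np.asarray(v).reshape(-1)[0]) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# table assembly


def extract_features(
    session: Session,
    pre_params: PreprocessParams | None = None,
    psd_params: PsdParams | None = None,
    subwindow_s: float | None = None,
) -> pd.DataFrame:
    """One row of the 10 metrics per (channel, segment) of a normalized session.

    With ``subwindow_s`` set, each segment is cut into consecutive windows of
    that length, the metrics are computed per window, and their mean is
    reported (per-window fatigue mode); by default each metric is computed
    once over the whole segment.
    """
    pre_params = pre_params or PreprocessParams()
    psd_params = (psd_params or PsdParams()).validate()
    rows = []
    for lab, seg in session.segments.items():
        if subwindow_s is None:
            blocks = [seg.samples]
        else:
            w = int(round(subwindow_s * session.fs))
            if w < psd_params.nperseg:
                raise ValueError("subwindow shorter than PSD segment length")
            n_win = seg.n_samples // w
            if n_win == 0:
                raise ValueError(
                    f"segment {lab.value} shorter than one sub-window"
                )
            blocks = [seg.samples[:, i * w : (i + 1) * w] for i in range(n_win)]
        acc: dict[str, np.ndarray] = {}
        for block in blocks:
            try:
                td = _td_batch(block, session.fs, pre_params, wfl_per_second=True)
                fd = _fd_batch(welch_psd(block, session.fs, psd_params))
            except ValueError as exc:
                raise ValueError(f"segment {lab.value}: {exc}") from exc
            for k, v in {**td, **fd}.items():
                acc.setdefault(k, []).append(np.asarray(v, dtype=np.float64))
        means = {k: np.mean(np.stack(v), axis=0) for k, v in acc.items()}
        for ci, ch in enumerate(session.channel_order):
            row = {
                "participant_id": session.participant_id,
                "channel": str(ch),
                "segment": lab.value,
            }
            row.update({m: float(means[m][ci]) for m in METRICS})
            rows.append(row)
    return pd.DataFrame(rows)


def feature_table_to_tidy(table: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide feature table into tidy (one metric value per row) form."""
    tidy = table.melt(
        id_vars=["participant_id", "channel", "segment"],
        value_vars=list(METRICS),
        var_name="metric",
        value_name="value",
    )
    split = tidy["channel"].str.rpartition("_")
    tidy.insert(1, "muscle", split[0])
    tidy.insert(2, "side", split[2])
    return tidy
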