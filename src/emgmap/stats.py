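"""Paired contrast families, normality screening, Bonferroni correction, and
the muscle x metric sensitivity matrix.

Four contrast families are defined over the protocol labels:

* ``compression_vs_control`` — each of the 8 compressions against its
  reference control (flat vs C2, curved vs C3); Bonferroni m = 8 per
  (muscle, metric).
* ``paddle_vs_paddle`` — flat vs curved for the same view; m = 4.
* ``angle_vs_angle`` — CC vs MLO for the same breast within a paddle; m = 4.
* ``control_vs_control`` — C1 vs C2 and C1 vs C3; m = 2.

Tests are two-sided paired t-tests on per-participant differences.  A
Lilliefors-corrected Kolmogorov-Smirnov normality p-value of the differences
is attached to every result but never gates the t-test.  Zero-variance
differences (which arise by construction, e.g. stdRMS of control vs control)
are flagged degenerate with p = 1 rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.diagnostic import lilliefors

from .features import METRICS
from .session_io import SegmentLabel

__all__ = [
    "FAMILIES",
    "Contrast",
    "ComparisonResult",
    "paired_t",
    "bonferroni",
    "family_contrasts",
    "run_family",
    "results_to_frame",
    "sensitivity_matrix",
]

FAMILIES = (
    "compression_vs_control",
    "paddle_vs_paddle",
    "angle_vs_angle",
    "control_vs_control",
)

_VIEWS = ("RCC", "LCC", "LMLO", "RMLO")


@dataclass(frozen=True)
class Contrast:
    family: str
    a: SegmentLabel
    b: SegmentLabel

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("contrast requires two distinct segments")


@dataclass
class ComparisonResult:
    channel: str
    metric: str
    contrast: Contrast
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p_raw: float
    p_adj: float
    significant: bool
    ks_p: float
    degenerate: bool = False


def family_contrasts(family: str) -> tuple[list[Contrast], int]:
    """The ordered contrast list and Bonferroni family size m."""
    L = SegmentLabel
    if family == "compression_vs_control":
        pairs = [(L(f"F_{v}"), L.C2) for v in _VIEWS] + [
            (L(f"C_{v}"), L.C3) for v in _VIEWS
        ]
        m = 8
    elif family == "paddle_vs_paddle":
        pairs = [(L(f"F_{v}"), L(f"C_{v}")) for v in _VIEWS]
        m = 4
    elif family == "angle_vs_angle":
        pairs = [
            (L.F_RCC, L.F_RMLO),
            (L.F_LCC, L.F_LMLO),
            (L.C_RCC, L.C_RMLO),
            (L.C_LCC, L.C_LMLO),
        ]
        m = 4
    elif family == "control_vs_control":
        pairs = [(L.C1, L.C2), (L.C1, L.C3)]
        m = 2
    else:
        raise ValueError(f"unknown family {family!r}")
    return [Contrast(family, a, b) for a, b in pairs], m


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided paired t on ``a - b`` plus a Lilliefors KS normality p-value.

    Returns ``(t, p_raw, ks_p)``.  Degenerate all-equal differences give
    ``(nan, 1.0, nan)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        return float("nan"), 1.0, float("nan")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * spstats.t.sf(abs(t), df=n - 1))
    try:
        _, ks_p = lilliefors(d, dist="norm", pvalmethod="table")
    except (ValueError, ZeroDivisionError):
        ks_p = float("nan")
    return t, p, float(ks_p)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Elementwise ``min(1, m * p)``."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(p_values, dtype=np.float64)
    return np.minimum(1.0, m * p)


def run_family(
    cohort_features: pd.DataFrame,
    family: str,
    alpha: float = 0.05,
    m: int | None = None,
    metrics: tuple[str, ...] = METRICS,
) -> list[ComparisonResult]:
    """All paired contrasts of one family over every (channel, metric).

    ``cohort_features`` is the wide feature table (rows keyed by
    participant_id, channel, segment).  ``m`` overrides the family's default
    Bonferroni size.  Results are sorted by (channel, metric, contrast
    order) and invariant to the row order of the input.
    """
    contrasts, m_default = family_contrasts(family)
    m = m_default if m is None else int(m)
    needed = sorted({c.a.value for c in contrasts} | {c.b.value for c in contrasts})
    participants = np.array(sorted(cohort_features["participant_id"].unique()))
    n = participants.size

    sub = cohort_features[cohort_features["segment"].isin(needed)]
    missing_rows = []
    pivots: dict[str, pd.DataFrame] = {}
    for seg in needed:
        piv = sub[sub["segment"] == seg].pivot(
            index="participant_id", columns="channel", values=list(metrics)
        )
        have = set(piv.index)
        lost = [p for p in participants if p not in have]
        if lost:
            missing_rows.append(f"{seg}: participants {lost}")
            continue
        pivots[seg] = piv.loc[participants]
    if missing_rows:
        raise ValueError(
            "missing segments for family "
            f"{family}: " + "; ".join(missing_rows)
        )

    channels = sorted(cohort_features["channel"].unique())
    results: list[ComparisonResult] = []
    for ch in channels:
        for metric in metrics:
            cell: list[ComparisonResult] = []
            for con in contrasts:
                a = pivots[con.a.value][(metric, ch)].to_numpy()
                b = pivots[con.b.value][(metric, ch)].to_numpy()
                t, p_raw, ks_p = paired_t(a, b)
                cell.append(
                    ComparisonResult(
                        channel=ch,
                        metric=metric,
                        contrast=con,
                        n=n,
                        mean_a=float(np.mean(a)),
                        sd_a=float(np.std(a, ddof=1)),
                        mean_b=float(np.mean(b)),
                        sd_b=float(np.std(b, ddof=1)),
                        t=t,
                        p_raw=p_raw,
                        p_adj=float("nan"),
                        significant=False,
                        ks_p=ks_p,
                        degenerate=bool(np.isnan(t)),
                    )
                )
            adj = bonferroni([r.p_raw for r in cell], m)
            for r, pa in zip(cell, adj):
                r.p_adj = float(pa)
                r.significant = bool(pa < alpha) and not r.degenerate
            results.extend(cell)
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "channel": r.channel,
                "metric": r.metric,
                "family": r.contrast.family,
                "segment_a": r.contrast.a.value,
                "segment_b": r.contrast.b.value,
                "n": r.n,
                "mean_a": r.mean_a,
                "sd_a": r.sd_a,
                "mean_b": r.mean_b,
                "sd_b": r.sd_b,
                "t": r.t,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "ks_p": r.ks_p,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_matrix(results: list[ComparisonResult]) -> pd.DataFrame:
    """Per (channel, metric): fraction of the 8 compressions significant.

    Only accepts compression_vs_control results; the denominator is fixed at
    8.  Returned as channels x metrics DataFrame of fractions in {0, 1/8,
    ..., 1}.
    """
    if not results:
        raise ValueError("no results supplied")
    bad = {r.contrast.family for r in results} - {"compression_vs_control"}
    if bad:
        raise ValueError(
            f"sensitivity matrix requires the compression_vs_control family, got {bad}"
        )
    df = results_to_frame(results)
    counts = (
        df.groupby(["channel", "metric"], sort=True)["significant"].sum().unstack()
    )
    metrics = [m for m in METRICS if m in counts.columns]
    return counts[metrics] / 8.0
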