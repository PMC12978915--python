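"""Summary products and the end-to-end pipeline.

Three artifacts summarize a processed cohort: a group table of
mean (SD) per (muscle, metric, paddle, view) with significance marks, a
muscle x metric sensitivity matrix (fraction of the 8 compressions whose
contrast was significant), and a per-view absolute percent-change map with
flat and curved paddles pooled.  ``run_pipeline`` chains
simulate/load -> preprocess -> features -> stats -> artifacts and aborts
with a stage-tagged error on failure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    METRICS,
    PsdParams,
    extract_features,
    feature_table_to_tidy,
)
from .preprocess import PreprocessParams, preprocess_session
from .session_io import (
    Cohort,
    SegmentLabel,
    read_cohort,
    segment_role,
    write_cohort,
)
from .stats import (
    ComparisonResult,
    results_to_frame,
    run_family,
    sensitivity_matrix,
)
from .synthetic_data import SimConfig, default_activation_map, simulate_cohort

__all__ = [
    "PercentChangeMap",
    "group_table",
    "format_group_table",
    "percent_change_map",
    "run_pipeline",
    "PipelineError",
]

_VIEWS = ("RCC", "LCC", "LMLO", "RMLO")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# group table


def group_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Long-form mean (SD) summary per (channel, metric, paddle, view).

    Built from compression-vs-control results: ``mean``/``sd`` describe the
    compression segment, ``control_mean``/``control_sd`` its reference
    control, and ``significant`` carries the Bonferroni-adjusted verdict.
    """
    if not results:
        raise ValueError("empty results")
    bad = {r.contrast.family for r in results} - {"compression_vs_control"}
    if bad:
        raise ValueError(f"group table requires compression_vs_control, got {bad}")
    rows = []
    for r in results:
        role = segment_role(r.contrast.a)
        rows.append(
            {
                "channel": r.channel,
                "metric": r.metric,
                "paddle": "flat" if role.paddle == "F" else "curved",
                "view": f"{role.side}{role.view}",
                "mean": r.mean_a,
                "sd": r.sd_a,
                "control_mean": r.mean_b,
                "control_sd": r.sd_b,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["channel", "metric", "paddle", "view"], ignore_index=True
    )


def _fmt(mean: float, sd: float, mark: bool = False) -> str:
    return f"{mean:.4g} ({sd:.3g})" + ("*" if mark else "")


def format_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable pivot: one row per (channel, metric, paddle), control
    and per-view ``mean (sd)`` cells, ``*`` marking adjusted significance."""
    out = []
    for (ch, metric, paddle), grp in table.groupby(
        ["channel", "metric", "paddle"], sort=True
    ):
        row = {"channel": ch, "metric": metric, "paddle": paddle}
        first = grp.iloc[0]
        row["control"] = _fmt(first["control_mean"], first["control_sd"])
        for view in _VIEWS:
            sub = grp[grp["view"] == view]
            if len(sub):
                r = sub.iloc[0]
                row[view] = _fmt(r["mean"], r["sd"], bool(r["significant"]))
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# percent-change map


@dataclass
class PercentChangeMap:
    """Absolute percent change per (muscle, side, view, metric), with flat
    and curved paddles pooled and C2+C3 pooled as the control population."""

    entries: pd.DataFrame          # muscle, side, view, metric, pct
    max_pct: pd.DataFrame          # muscle x metric, max over sides and views


def percent_change_map(features: pd.DataFrame) -> PercentChangeMap:
    tidy = feature_table_to_tidy(features)
    ctrl = tidy[tidy["segment"].isin(["C2", "C3"])]
    rows = []
    for (muscle, side, metric), grp in tidy.groupby(
        ["muscle", "side", "metric"], sort=True
    ):
        ctrl_vals = grp[grp["segment"].isin(["C2", "C3"])]["value"]
        mean_ctrl = ctrl_vals.mean()
        if mean_ctrl == 0 or not np.isfinite(mean_ctrl):
            raise ValueError(f"zero control mean for {muscle}_{side} / {metric}")
        for view in _VIEWS:
            comp = grp[grp["segment"].isin([f"F_{view}", f"C_{view}"])]["value"]
            if comp.empty:
                continue
            pct = abs(comp.mean() - mean_ctrl) / abs(mean_ctrl) * 100.0
            rows.append(
                {
                    "muscle": muscle,
                    "side": side,
                    "view": view,
                    "metric": metric,
                    "pct": pct,
                }
            )
    entries = pd.DataFrame(rows)
    if entries.empty:
        raise ValueError("no compression segments in feature table")
    max_pct = (
        entries.groupby(["muscle", "metric"], sort=True)["pct"].max().unstack()
    )
    max_pct = max_pct[[m for m in METRICS if m in max_pct.columns]]
    return PercentChangeMap(entries, max_pct)


def render_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Plain matrix heatmap of a channels x metrics table (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.35 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def cohort_features(
    cohort: Cohort,
    pre_params: PreprocessParams | None = None,
    psd_params: PsdParams | None = None,
    subwindow_s: float | None = None,
) -> pd.DataFrame:
    """Preprocess every session and stack the per-session feature tables."""
    pre_params = pre_params or PreprocessParams()
    psd_params = psd_params or PsdParams()
    tables = []
    for session in cohort:
        normalized, _ = _stage(
            "normalize", preprocess_session, session, pre_params
        )
        tables.append(
            _stage(
                "features",
                extract_features,
                normalized,
                pre_params,
                psd_params,
                subwindow_s,
            )
        )
    return pd.concat(tables, ignore_index=True)


def run_pipeline(config, out_dir=None) -> Path:
    """Run simulate/load -> preprocess -> features -> stats -> artifacts.

    ``config`` is a YAML path or dict with optional blocks ``simulate`` (or
    ``input``), ``preprocess``, ``psd``, ``stats``, and ``out``.  Returns the
    artifact directory.  Every failure raises :class:`PipelineError` with the
    failing stage in the message.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out", "artifacts"))
    out.mkdir(parents=True, exist_ok=True)

    pre_params = PreprocessParams(**cfg.get("preprocess", {}))
    psd_params = PsdParams(**cfg.get("psd", {}))
    stats_cfg = cfg.get("stats", {})
    alpha = float(stats_cfg.get("alpha", 0.05))
    families = stats_cfg.get("families", ["compression_vs_control"])

    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        gain_overrides = sim.pop("gains", None)
        amap = default_activation_map()
        if gain_overrides:
            from .session_io import Muscle

            gains = dict(amap.gain)
            gains.update({Muscle(k): float(v) for k, v in gain_overrides.items()})
            amap = default_activation_map(gain=gains)
        sim_config = _stage("simulate", SimConfig, **sim)
        cohort = _stage("simulate", simulate_cohort, sim_config, amap)
    elif "input" in cfg:
        inp = dict(cfg["input"])
        path = inp.pop("path")
        inp.setdefault("require_reference_controls", False)
        cohort = _stage("load", read_cohort, path, inp)
    else:
        raise PipelineError("config", "need a 'simulate' or 'input' block")

    features = cohort_features(cohort, pre_params, psd_params)
    feature_table_to_tidy(features).to_csv(out / "features.csv", index=False)

    all_results = []
    comp_results = None
    for family in families:
        res = _stage("stats", run_family, features, family, alpha)
        all_results.extend(res)
        if family == "compression_vs_control":
            comp_results = res
    results_to_frame(all_results).to_csv(out / "comparisons.csv", index=False)

    if comp_results:
        _stage("report", sensitivity_matrix, comp_results).to_csv(
            out / "sensitivity_matrix.csv"
        )
        _stage("report", group_table, comp_results).to_csv(
            out / "group_table.csv", index=False
        )
        pcm = _stage("report", percent_change_map, features)
        pcm.entries.to_csv(out / "percent_change.csv", index=False)
        pcm.max_pct.to_csv(out / "percent_change_max.csv")

    manifest = {
        "emgmap_version": __version__,
        "config": _jsonable(cfg),
        "alpha": alpha,
        "families": list(families),
        "n_sessions": len(cohort),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
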