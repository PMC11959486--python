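"""Group-level aggregation, comparison statistics and pipeline orchestration.

Group comparisons use an unpaired t-test — Welch's unequal-variance form
by default, with the pooled Student form available for sensitivity —
reporting mean ± s.e.m. per group, percent change versus control
(100 × (control − group) / control, so a reduction is positive), the t
statistic and p-value.  No multiple-testing correction is applied.
Significance markers: ns, * (p<0.05), ** (p<0.005), *** (p<0.0001).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .core_image import VoxelGeometry
from .mejp import amplitude_distribution, detect_mejps, mejp_summary, qc_trace
from .shell_intensity import ShellConfig, quantify_nmj_intensity

__all__ = [
    "GroupSummary",
    "compare_groups",
    "significance_marker",
    "parse_config",
    "run_pipeline",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    percent_change_vs_control: float | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    tails: str | None = None
    marker: str | None = None


def significance_marker(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    control,
    treatment,
    tails: str = "two",
    *,
    direction: str = "greater",
    equal_var: bool = False,
    control_name: str = "control",
    treatment_name: str = "treatment",
) -> tuple[GroupSummary, GroupSummary]:
    """Unpaired t-test between a control and a treatment group.

    ``tails="one"`` tests the hypothesis that the treatment mean is
    ``direction`` ("greater" or "less") than the control mean.  Percent
    change is relative to the control mean with reductions positive.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if len(c) < 2 or len(t) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(c).all() and np.isfinite(t).all()):
        raise ValueError("values must be finite")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if tails == "one" and direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    mean_c, mean_t = float(c.mean()), float(t.mean())
    if mean_c == 0:
        raise ValueError("control mean is zero: percent change undefined")
    alternative = "two-sided" if tails == "two" else direction
    res = scipy.stats.ttest_ind(t, c, equal_var=equal_var, alternative=alternative)
    pct = 100.0 * (mean_c - mean_t) / mean_c
    ctrl = GroupSummary(
        group=control_name,
        n=len(c),
        mean=mean_c,
        sem=float(scipy.stats.sem(c)),
        percent_change_vs_control=0.0,
    )
    trt = GroupSummary(
        group=treatment_name,
        n=len(t),
        mean=mean_t,
        sem=float(scipy.stats.sem(t)),
        percent_change_vs_control=pct,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tails=tails,
        marker=significance_marker(float(res.pvalue)),
    )
    return ctrl, trt


def parse_config(path: str | Path) -> dict[str, str]:
    """Flat key=value config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split("=", 1)
        cfg[key.strip()] = val.strip()
    return cfg


def _write_log(path: Path, params: dict) -> None:
    lines = [f"{k} = {params[k]}" for k in sorted(params)]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: dict[str, str] | str | Path, out_dir: str | Path | None = None):
    """Execute a configured stage batch and write a report bundle.

    Supported stages: ``shell_batch`` (phantom generation → shell
    intensity → group comparison) and ``mejp_batch`` (trace generation →
    QC → detection → summaries → group comparison).  Outputs: a per-NMJ
    (or per-recording) CSV, a group CSV, a JSON summary and a plain-text
    log recording every parameter and seed.  Identical config and seeds
    reproduce byte-identical outputs.
    """
    if not isinstance(config, dict):
        config = parse_config(config)
    cfg = dict(config)
    stage = cfg.get("stage")
    out = Path(out_dir or cfg.get("out_dir", "synaptoquant_out"))
    out.mkdir(parents=True, exist_ok=True)
    if stage == "shell_batch":
        return _run_shell_batch(cfg, out)
    if stage == "mejp_batch":
        return _run_mejp_batch(cfg, out)
    raise ValueError(f"unknown or missing stage: {stage!r}")


def _run_shell_batch(cfg: dict[str, str], out: Path):
    from .synthetic_data import make_nmj_stack

    n_per_group = int(cfg.get("n_per_group", 0))
    if n_per_group < 2:
        raise ValueError("shell_batch needs n_per_group >= 2")
    seed = int(cfg.get("seed", 0))
    noise = float(cfg.get("noise", 3.0))
    effects = {
        "control": float(cfg.get("group_effect_control", 1.0)),
        "treatment": float(cfg.get("group_effect_treatment", 0.5)),
    }
    channel = cfg.get("channel", "BSpec")
    geometry = VoxelGeometry(
        float(cfg.get("pixel_size", 0.21)), float(cfg.get("z_step", 0.24))
    )
    shell_cfg = ShellConfig(
        struct_radius_px=int(cfg.get("struct_radius_px", 2)),
        roi_size_px=int(cfg.get("roi_size_px", 47)),
    )

    rows = []
    values: dict[str, list[float]] = {g: [] for g in effects}
    for gi, (group, effect) in enumerate(sorted(effects.items())):
        for i in range(n_per_group):
            s = seed + 1000 * gi + i
            stack, truth = make_nmj_stack(
                n_boutons=1, geometry=geometry, group_effect=effect, noise=noise, seed=s
            )
            cz, cy, cx = truth.bouton_centers[0]
            center = (
                int(round(cy / geometry.pixel_size_xy - 0.5)),
                int(round(cx / geometry.pixel_size_xy - 0.5)),
            )
            recs = quantify_nmj_intensity(
                stack, center, shell_cfg, nmj_id=f"{group}_{i}"
            )
            for r in recs:
                rows.append({"group": group, "seed": s, **asdict(r)})
                if r.channel == channel:
                    values[group].append(r.shell_mean)

    ctrl, trt = compare_groups(
        values["control"], values["treatment"], tails=cfg.get("tails", "two")
    )
    return _write_bundle(
        out,
        per_rows=rows,
        summaries=[ctrl, trt],
        params={**cfg, "stage": "shell_batch", "measured_channel": channel},
        extra={"measured_channel": channel},
    )


def _run_mejp_batch(cfg: dict[str, str], out: Path):
    from .synthetic_data import MEJP_CONTROL, MEJP_DEPLETED, make_mejp_trace

    n_per_group = int(cfg.get("n_per_group", 0))
    if n_per_group < 2:
        raise ValueError("mejp_batch needs n_per_group >= 2")
    seed = int(cfg.get("seed", 0))
    duration = float(cfg.get("duration", 108.0))
    threshold = float(cfg.get("threshold", 0.3))
    rmp_cutoff = float(cfg.get("rmp_cutoff", -60.0))
    conditions = {"control": MEJP_CONTROL, "treatment": MEJP_DEPLETED}

    rows = []
    freqs: dict[str, list[float]] = {g: [] for g in conditions}
    amps: dict[str, list[float]] = {g: [] for g in conditions}
    for gi, (group, cond) in enumerate(sorted(conditions.items())):
        for i in range(n_per_group):
            s = seed + 1000 * gi + i
            trace, _ = make_mejp_trace(duration=duration, seed=s, **cond)
            qc = qc_trace(trace, rmp_cutoff)
            if not qc:
                rows.append({"group": group, "seed": s, "qc": qc.reason})
                continue
            events = detect_mejps(trace, threshold)
            freq, amp = mejp_summary(events, trace.duration)
            _, frac = amplitude_distribution(events, np.arange(0.0, 3.01, 0.2))
            rows.append(
                {
                    "group": group,
                    "seed": s,
                    "qc": "pass",
                    "frequency_hz": freq,
                    "mean_amplitude_mV": amp,
                    "fraction_above_0.8mV": frac,
                }
            )
            freqs[group].append(freq)
            amps[group].append(amp)

    cf, tf = compare_groups(
        freqs["control"], freqs["treatment"],
        control_name="control:frequency", treatment_name="treatment:frequency",
    )
    ca, ta = compare_groups(
        amps["control"], amps["treatment"],
        control_name="control:amplitude", treatment_name="treatment:amplitude",
    )
    return _write_bundle(
        out,
        per_rows=rows,
        summaries=[cf, tf, ca, ta],
        params={**cfg, "stage": "mejp_batch"},
        extra={},
    )


def _write_bundle(out: Path, per_rows, summaries, params, extra):
    per_df = pd.DataFrame(per_rows)
    grp_df = pd.DataFrame([asdict(s) for s in summaries])
    per_path = out / "per_nmj.csv"
    grp_path = out / "groups.csv"
    per_df.to_csv(per_path, index=False)
    grp_df.to_csv(grp_path, index=False)
    summary = {"groups": [asdict(s) for s in summaries], **extra}
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_log(out / "run.log", params)
    return {
        "per_nmj": per_df,
        "groups": grp_df,
        "summary": summary,
        "paths": {
            "per_nmj": per_path,
            "groups": grp_path,
            "summary": json_path,
            "log": out / "run.log",
        },
    }
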