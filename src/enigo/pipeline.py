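"""End-to-end orchestration: simulate -> behavior -> preprocess -> sensor
statistics -> source estimation -> source statistics, with one config.

Detected sensor-space sustained periods automatically become the
periods of interest for the source analyses.  The consolidated report
(JSON + Markdown) lists behavioral statistics, sustained periods and
surviving source clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import headmodel as hm
from . import inverse as inv
from . import masstats as ms
from . import preprocess as pp
from . import srcstats as ss
from .synth import (
    EegSimConfig,
    TaskConfig,
    default_group_profiles,
    simulate_eeg,
    simulate_group_study,
)

__all__ = ["RunConfig", "run_all", "epoch_count_control"]


@dataclass
class RunConfig:
    n_si: int = 15
    n_ii: int = 17
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    eeg: EegSimConfig = field(default_factory=EegSimConfig)
    beg_blocks: tuple[int, ...] = (1, 2, 3, 4)
    end_blocks: tuple[int, ...] = (9, 10, 11, 12)
    head_radius: float = hm.DEFAULT_HEAD_RADIUS
    grid_spacing: float = 6.0
    grid_target_n: int = 3005
    artifact_threshold: float = 80.0
    baseline: bool = False
    sdt_c_sign: str = "paper"
    alpha: float = 0.05
    electrode_frac: float = 0.10
    min_frames: int = 11
    calibrate_duration: bool = False
    n_perm: int = 1000
    k_e: int = 15
    cluster_radius: float = 8.5
    lambda_snr: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = dict(raw)
        if "task" in kwargs:
            kwargs["task"] = TaskConfig(**kwargs["task"])
        if "eeg" in kwargs:
            eeg = dict(kwargs["eeg"])
            if "effect_pattern" in eeg:
                eeg["effect_pattern"] = {
                    tuple(k.split("/")): v for k, v in eeg["effect_pattern"].items()
                }
            kwargs["eeg"] = EegSimConfig(**eeg)
        for key in ("beg_blocks", "end_blocks"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def epoch_count_control(
    counts: np.ndarray, groups: np.ndarray
) -> bh.MixedAnovaResult:
    """Mixed ANOVA on per-condition epoch counts (design control analysis)."""
    return bh.mixed_anova_2x2(np.asarray(counts, dtype=float), groups)


def _behavior_report(study: pd.DataFrame, cfg: RunConfig) -> dict:
    summaries = bh.summarize_study(
        study,
        beg_blocks=cfg.beg_blocks,
        end_blocks=cfg.end_blocks,
        c_sign=cfg.sdt_c_sign,
    )
    beg = summaries[summaries["session"] == "BEG"]
    si = beg[beg["group"] == "SI"]
    ii = beg[beg["group"] == "II"]

    report: dict = {"per_subject": summaries.to_dict("records"), "tests": {}}
    for measure in ("rt_mean", "fa_rate", "d_prime", "c_criterion"):
        t = bh.pooled_t(si[measure].to_numpy(), ii[measure].to_numpy())
        report["tests"][f"beg_{measure}_pooled_t"] = t.as_dict()

    lev_f, lev_p = bh.levene_test(
        si["fa_rate"].to_numpy(), ii["fa_rate"].to_numpy()
    )
    report["tests"]["beg_fa_rate_levene"] = {
        "test": "levene", "statistic": lev_f, "p": lev_p,
    }
    if lev_p < cfg.alpha:
        w = bh.welch_t(si["fa_rate"].to_numpy(), ii["fa_rate"].to_numpy())
        report["tests"]["beg_fa_rate_welch_t"] = w.as_dict()

    for measure in ("rt_mean", "fa_rate", "d_prime", "c_criterion"):
        wide = summaries.pivot(
            index=["subject", "group"], columns="session", values=measure
        ).sort_index()
        groups = np.array([g for _, g in wide.index])
        y = np.column_stack([wide["BEG"].to_numpy(), wide["END"].to_numpy()])
        res = bh.mixed_anova_2x2(y, groups)
        report["tests"][f"{measure}_group_x_session_anova"] = res.as_dict()

    sat = bh.sat_correlations(summaries, alpha=cfg.alpha)
    report["tests"]["sat_correlations"] = sat.to_dict("records")

    ks_rows = {}
    for (group, session), cell in summaries.groupby(["group", "session"]):
        x = cell["fa_rate"].to_numpy()
        try:
            d, p = bh.ks_normality(x)
        except ValueError:
            d, p = float("nan"), float("nan")
        ks_rows[f"{group}_{session}_fa_rate"] = {"D": d, "p": p}
    report["tests"]["ks_normality"] = ks_rows
    return report


def _subject_erps(
    epochs, cfg: RunConfig
) -> tuple[dict[str, object], dict[str, int]]:
    """Per-condition ERPs (BEG_HIT, BEG_CR, END_CR) for one subject."""
    montage = hm.standard_64_montage(cfg.head_radius)
    clean = pp.reject_artifacts(epochs, threshold=cfg.artifact_threshold)
    if cfg.baseline:
        clean = pp.baseline_correct(clean)

    beg = set(cfg.beg_blocks)
    end = set(cfg.end_blocks)
    sets = {}
    for name, blocks in (("BEG", beg), ("END", end)):
        in_sess = np.isin(clean.blocks, list(blocks))
        hit = clean.select(np.flatnonzero(in_sess & (clean.labels == "HIT")))
        cr = clean.select(np.flatnonzero(in_sess & (clean.labels == "CR")))
        hit, cr = pp.match_trial_counts(hit, cr)
        sets[f"{name}_HIT"] = hit
        sets[f"{name}_CR"] = cr

    bad = list(epochs.meta.get("bad_channels", []))
    erps, counts = {}, {}
    for name in ("BEG_HIT", "BEG_CR", "END_CR"):
        es = sets[name]
        counts[name] = es.n_epochs
        if es.n_epochs == 0:
            raise RuntimeError(
                f"subject {epochs.meta.get('subject')}: no epochs left for {name}"
            )
        erp = pp.average_erp(es, condition=name)
        if bad:
            erp = pp.interpolate_bad_channels(erp, montage, bad)
        erps[name] = erp
    return erps, counts


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    log: list[str] = []
    report: dict = {"config": {"seed": config.seed}, "log": log}

    # --- behavioral stage -------------------------------------------------
    study = simulate_group_study(
        config.n_si, config.n_ii, default_group_profiles(), config.task,
        seed=config.seed,
    )
    log.append(f"simulated {config.n_si} SI + {config.n_ii} II subjects")
    report["behavior"] = _behavior_report(study, config)

    # --- head model -------------------------------------------------------
    space = hm.build_source_grid(
        head_radius=config.head_radius,
        spacing=config.grid_spacing,
        target_n=config.grid_target_n,
    )
    montage = hm.standard_64_montage(config.head_radius)
    lf = hm.compute_lead_field(space, montage)
    log.append(f"source grid: {space.n_nodes} nodes at {space.spacing} mm")

    # --- EEG simulation + preprocessing ----------------------------------
    eeg = simulate_eeg(
        study, lf, config.eeg,
        beg_blocks=config.beg_blocks, end_blocks=config.end_blocks,
    )
    subjects = sorted(eeg.keys())
    erps, counts, groups = {}, {}, []
    for subj in subjects:
        subj_erps, subj_counts = _subject_erps(eeg[subj], config)
        erps[subj] = subj_erps
        counts[subj] = subj_counts
        groups.append(eeg[subj].meta["group"])
        n_rej = eeg[subj].n_epochs - sum(subj_counts.values())
        log.append(
            f"{subj}: kept {subj_counts} epochs "
            f"({n_rej} rejected/unmatched of {eeg[subj].n_epochs})"
        )
    groups = np.asarray(groups)

    # --- epoch-count control ANOVAs --------------------------------------
    gxs_counts = np.array(
        [[counts[s]["BEG_HIT"], counts[s]["BEG_CR"]] for s in subjects], float
    )
    gxsess_counts = np.array(
        [[counts[s]["BEG_CR"], counts[s]["END_CR"]] for s in subjects], float
    )
    report["epoch_count_control"] = {
        "group_x_stimulus": epoch_count_control(gxs_counts, groups).as_dict(),
        "group_x_session": epoch_count_control(gxsess_counts, groups).as_dict(),
    }

    # --- sensor-space mass statistics ------------------------------------
    designs = {
        "group_x_stimulus": ("BEG_HIT", "BEG_CR"),
        "group_x_session": ("BEG_CR", "END_CR"),
    }
    times = erps[subjects[0]]["BEG_HIT"].times
    report["sensor_stats"] = {}
    sensor_data = {}
    for design, (c1, c2) in designs.items():
        data = np.stack(
            [np.stack([erps[s][c1].data, erps[s][c2].data]) for s in subjects]
        )
        sensor_data[design] = data
        min_frames = config.min_frames
        if config.calibrate_duration:
            min_frames = ms.permutation_duration_threshold(
                data, groups, n_perm=config.n_perm, alpha=config.alpha,
                electrode_frac=config.electrode_frac, seed=config.seed,
            )
            log.append(f"{design}: calibrated duration criterion {min_frames}")
        stat_map = ms.pointwise_interaction(data, groups, times, design=design)
        periods = ms.find_sustained_periods(
            stat_map, electrode_frac=config.electrode_frac,
            min_frames=min_frames, alpha=config.alpha,
        )
        report["sensor_stats"][design] = {
            "min_frames": min_frames,
            "periods": [
                {
                    "start_ms": p.start_ms, "end_ms": p.end_ms,
                    "frames": p.frames,
                    "peak_electrode_fraction": p.peak_electrode_fraction,
                }
                for p in periods
            ],
        }
        report["sensor_stats"][design]["_periods_obj"] = periods

    # --- source analyses over detected periods ---------------------------
    op = inv.build_laura_operator(lf, space, lambda_snr=config.lambda_snr)
    report["source_stats"] = {}
    for design, (c1, c2) in designs.items():
        periods = report["sensor_stats"][design].pop("_periods_obj")
        per_period = []
        for p in periods:
            dens = np.empty((len(subjects), 2, space.n_nodes))
            for i, s in enumerate(subjects):
                for j, cond in enumerate((c1, c2)):
                    topo = inv.average_erp_period(
                        erps[s][cond], (p.start_ms, p.end_ms)
                    )
                    dens[i, j] = inv.apply_inverse(op, topo).density
            node_map = ss.nodewise_interaction(dens, groups, design=design)
            clusters = ss.find_clusters(
                node_map.p, space, alpha=config.alpha, k_e=config.k_e,
                radius=config.cluster_radius, f=node_map.f,
            )
            per_period.append(
                {
                    "period_ms": [p.start_ms, p.end_ms],
                    "clusters": [
                        {
                            "size": c.size,
                            "peak_node": c.peak_node,
                            "peak_f": c.peak_f,
                            "peak_xyz": space.nodes[c.peak_node].tolist(),
                            "nodes": c.nodes.tolist(),
                        }
                        for c in clusters
                    ],
                }
            )
        report["source_stats"][design] = per_period

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        study.to_csv(out / "study_log.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        (out / "report.md").write_text(render_markdown(report))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def render_markdown(report: dict) -> str:
    """Compact human-readable summary mirroring the behavioral-table layout."""
    lines = ["# Pipeline report", ""]
    lines.append("## Behavioral tests")
    lines.append("| test | statistic | df | p | effect size |")
    lines.append("|---|---|---|---|---|")
    for name, t in report["behavior"]["tests"].items():
        if isinstance(t, dict) and "statistic" in t:
            lines.append(
                f"| {name} | {t['statistic']:.3f} | {t.get('df', '')} "
                f"| {t['p']:.4f} | {t.get('effect_size', '')} |"
            )
    lines.append("")
    lines.append("## Sustained sensor-space periods")
    for design, res in report["sensor_stats"].items():
        lines.append(f"### {design} (min_frames={res['min_frames']})")
        if not res["periods"]:
            lines.append("- none")
        for p in res["periods"]:
            lines.append(
                f"- {p['start_ms']:.1f}-{p['end_ms']:.1f} ms "
                f"({p['frames']} frames, peak electrode fraction "
                f"{p['peak_electrode_fraction']:.2f})"
            )
    lines.append("")
    lines.append("## Source clusters")
    for design, per_period in report["source_stats"].items():
        lines.append(f"### {design}")
        if not per_period:
            lines.append("- no periods")
        for entry in per_period:
            a, b = entry["period_ms"]
            lines.append(f"- period {a:.1f}-{b:.1f} ms:")
            if not entry["clusters"]:
                lines.append("  - no clusters survive")
            for c in entry["clusters"]:
                x, y, z = c["peak_xyz"]
                lines.append(
                    f"  - k={c['size']}, peak F={c['peak_f']:.2f} "
                    f"at ({x:.0f}, {y:.0f}, {z:.0f}) mm"
                )
    lines.append("")
    return "\n".join(lines)
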