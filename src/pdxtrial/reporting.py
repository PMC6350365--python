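"""Figures and the per-pattern analysis pipeline.

Figure conventions: response levels keep a fixed palette across every figure
(CR green, PR light green, SD grey, PD red); growth curves show the arm
center with an SEM band; waterfall bars are sorted worst-to-best response
left to right.  Vector output is rendered deterministically (fixed SVG hash
salt, no timestamp metadata) so identical inputs give byte-identical files.

:func:`run_pipeline` routes the analyses appropriate to each trial design:
between-arm statistics need replicate animals per arm (1AN, TAN); TGI needs a
control arm within each tumor (1AN, T1N, TAN); response labeling applies to
all four patterns, including the single-animal-per-arm mouse-clinical-trial
design (TA1).
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import response_level, tgi, trial_data, volume_stats
from .trial_data import TrialDataError, TrialDataset

__all__ = [
    "LEVEL_COLORS",
    "plot_growth_curves",
    "plot_animal_curves",
    "plot_tgi_series",
    "plot_response_bar",
    "plot_waterfall",
    "run_pipeline",
]

LEVEL_COLORS = {"CR": "#1a9850", "PR": "#91cf60", "SD": "#9e9e9e", "PD": "#d73027"}

def _finish(fig, out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    # strip timestamps and fix the id salt so identical inputs render
    # byte-identical vector files
    with plt.rc_context({"svg.hashsalt": "pdxtrial"}):
        meta = {"Date": None} if out.suffix.lower() in (".svg", ".pdf") else None
        fig.savefig(out, metadata=meta)
    plt.close(fig)
    return out


def plot_growth_curves(summaries: pd.DataFrame, out: str | Path) -> Path:
    """Arm-level growth curves (center line with SEM band) per tumor."""
    tumors = summaries["tumor_id"].unique()
    fig, axes = plt.subplots(
        1, len(tumors), figsize=(4.5 * len(tumors), 3.5), squeeze=False
    )
    for ax, tumor in zip(axes[0], tumors):
        sub = summaries[summaries["tumor_id"] == tumor]
        for arm, g in sub.groupby("arm"):
            g = g.sort_values("day")
            ax.plot(g["day"], g["center"], marker="o", ms=3, label=str(arm))
            band = g.dropna(subset=["sem"])
            if not band.empty:
                ax.fill_between(
                    band["day"],
                    band["center"] - band["sem"],
                    band["center"] + band["sem"],
                    alpha=0.2,
                )
        ax.set_xlabel("days post T0")
        ax.set_ylabel("tumor volume (mm³)")
        ax.set_title(str(tumor))
        ax.legend(fontsize=7)
    fig.tight_layout()
    return _finish(fig, out)


def plot_animal_curves(ds: TrialDataset, out: str | Path) -> Path:
    """Per-animal spaghetti plot, colored by arm."""
    df = ds.records
    arms = sorted(df["arm"].unique())
    cmap = plt.get_cmap("tab10")
    colors = {arm: cmap(i % 10) for i, arm in enumerate(arms)}
    fig, ax = plt.subplots(figsize=(6, 4))
    seen = set()
    for (arm, _animal), g in df.groupby(["arm", "animal_id"]):
        g = g.sort_values("day")
        ax.plot(
            g["day"], g["volume"], color=colors[arm], lw=0.9, alpha=0.8,
            label=arm if arm not in seen else None,
        )
        seen.add(arm)
    ax.set_xlabel("days post T0")
    ax.set_ylabel("tumor volume (mm³)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _finish(fig, out)


def plot_tgi_series(series: list[tgi.TGISeries], out: str | Path) -> Path:
    """TGI over time, one line per treatment arm; undefined rows are not drawn."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series:
        ok = s.rows[s.rows["defined"]]
        if ok.empty:
            continue
        ax.plot(ok["day"], ok["tgi_percent"], marker="o", ms=3,
                label=f"{s.arm} ({s.f_kind})")
    ax.axhline(0, color="k", lw=0.6)
    ax.axhline(100, color="k", lw=0.6, ls=":")
    ax.set_xlabel("days post T0")
    ax.set_ylabel("TGI (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _finish(fig, out)


def plot_response_bar(
    summaries: list[response_level.ArmResponseSummary], out: str | Path
) -> Path:
    """Stacked per-arm counts of CR/PR/SD/PD, arms ordered by efficacy."""
    ordered = response_level.rank_arms(summaries)
    labels = [s.arm for s in ordered]
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(labels)), 4))
    bottoms = np.zeros(len(ordered))
    for level in response_level.LEVELS:
        heights = np.array([s.counts.get(level, 0) for s in ordered], dtype=float)
        ax.bar(labels, heights, bottom=bottoms, color=LEVEL_COLORS[level], label=level)
        bottoms += heights
    ax.set_ylabel("animals")
    ax.legend(fontsize=7)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    return _finish(fig, out)


def plot_waterfall(
    calls: list[response_level.ResponseCall],
    metric: str = "best_avg_response",
    out: str | Path = "waterfall.svg",
    thresholds: response_level.Thresholds | None = None,
) -> Path:
    """Waterfall plot: one bar per animal, sorted descending, colored by level.

    Horizontal guides mark the active standard's response cutoffs for the
    chosen metric.
    """
    if not calls:
        raise TrialDataError("no response calls to plot")
    th = thresholds or response_level.Thresholds()

    def value(c):
        if metric == "best_avg_response" and c.best_avg_response is not None:
            return c.best_avg_response
        if c.best_response is not None:
            return c.best_response
        return c.metrics.get("end_delta_pct", 0.0)

    ordered = sorted(calls, key=lambda c: (-value(c), c.animal_id))
    vals = [value(c) for c in ordered]
    colors = [LEVEL_COLORS[c.level] for c in ordered]
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(ordered)), 4))
    ax.bar(range(len(ordered)), vals, color=colors)
    standard = ordered[0].standard
    if standard == "npdxe":
        guides = (th.npdxe_cr[1], th.npdxe_pr[1], th.npdxe_sd[1]) \
            if metric == "best_avg_response" else \
            (th.npdxe_cr[0], th.npdxe_pr[0], th.npdxe_sd[0])
    elif standard == "rc":
        guides = (th.rc_cr, th.rc_pr, th.rc_pd)
    else:
        guides = ()
    for g in guides:
        ax.axhline(g, color="k", lw=0.5, ls="--")
    ax.set_xticks(range(len(ordered)))
    ax.set_xticklabels([c.animal_id for c in ordered], rotation=90, fontsize=5)
    ax.set_ylabel(f"{metric} (%)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=LEVEL_COLORS[l])
               for l in response_level.LEVELS]
    ax.legend(handles, response_level.LEVELS, fontsize=7)
    fig.tight_layout()
    return _finish(fig, out)


# ---------------------------------------------------------------------------
# pipeline


def _stats_block(ds: TrialDataset, tumor: str, n_perm: int, seed, adjust: str):
    rates = volume_stats.endpoint_values(
        ds.subset(tumor_id=tumor), "growth_rate", "slope_log"
    )
    by_arm = {a: g["value"].to_numpy() for a, g in rates.groupby("arm")}
    rows = []
    anova = volume_stats.one_way_test(by_arm, parametric=True)
    kw = volume_stats.one_way_test(by_arm, parametric=False)
    for r in (anova, kw):
        rows.append((tumor, r.method, "arm", r.statistic,
                     "/".join(str(d) for d in r.df), r.p_value, r.notes))
    perm = volume_stats.permutation_curve_test(
        ds, tumor_id=tumor, n_perm=n_perm, seed=seed, adjust=adjust
    )
    for _, pr in perm.pairs.iterrows():
        rows.append((tumor, "permutation", f"{pr.arm_a} vs {pr.arm_b}",
                     pr.statistic, str(pr.n_perm), pr.p_adjusted, pr.note))
    return pd.DataFrame(
        rows, columns=["tumor_id", "method", "term", "statistic", "df", "p", "note"]
    )


def run_pipeline(
    ds: TrialDataset,
    out_dir: str | Path,
    pattern: str = "auto",
    standard: str = "npdxe",
    thresholds: response_level.Thresholds | None = None,
    f_kinds: tuple[str, ...] = ("diff",),
    n_perm: int = 1000,
    seed: int | None = 0,
    adjust: str = "holm",
    figure_format: str = "svg",
) -> dict:
    """Run every analysis the trial design supports and write a result bundle.

    Returns the JSON-serializable summary (also written to ``summary.json``)
    naming every table and figure produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = trial_data.validate(ds)
    if not report.ok:
        raise TrialDataError(
            f"validation failed with {len(report.fatal)} fatal issue(s): "
            + "; ".join(m for _, _, m in report.fatal[:5])
        )
    code = pattern if pattern != "auto" else trial_data.infer_pattern(ds).code
    do_stats = code in ("1AN", "TAN")
    do_tgi = code in ("1AN", "T1N", "TAN")
    artifacts: list[str] = []

    def save_table(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        artifacts.append(str(p))

    summaries = trial_data.summarize_arm(ds)
    save_table(summaries, "arm_summary.tsv")
    artifacts.append(str(plot_growth_curves(summaries, out_dir / f"growth_curves.{figure_format}")))
    artifacts.append(str(plot_animal_curves(ds, out_dir / f"animal_curves.{figure_format}")))

    if do_stats:
        frames = [_stats_block(ds, t, n_perm, seed, adjust) for t in ds.tumors]
        save_table(pd.concat(frames, ignore_index=True), "stats.tsv")

    if do_tgi:
        all_series: list[tgi.TGISeries] = []
        for kind in f_kinds:
            all_series.extend(tgi.compute_tgi(ds, f_kind=kind))
        save_table(tgi.tgi_table(all_series), "tgi.tsv")
        artifacts.append(str(plot_tgi_series(all_series, out_dir / f"tgi_series.{figure_format}")))

    calls = response_level.label_dataset(ds, standard=standard, th=thresholds)
    save_table(response_level.calls_table(calls), "calls.tsv")
    arm_sums = response_level.summarize_responses(calls, by_tumor=(code in ("1AN", "TAN")))
    idx_rows = [
        (s.tumor_id, s.arm, len(s.calls), s.counts["CR"], s.counts["PR"],
         s.counts["SD"], s.counts["PD"], s.rr_pct, s.dcr_pct)
        for s in response_level.rank_arms(arm_sums)
    ]
    save_table(
        pd.DataFrame(idx_rows, columns=["tumor_id", "arm", "n", "CR", "PR",
                                        "SD", "PD", "rr_pct", "dcr_pct"]),
        "response_summary.tsv",
    )
    artifacts.append(str(plot_response_bar(arm_sums, out_dir / f"response_bar.{figure_format}")))
    metric = "best_avg_response" if standard == "npdxe" else "best_response"
    artifacts.append(str(plot_waterfall(
        calls, metric=metric, out=out_dir / f"waterfall.{figure_format}",
        thresholds=thresholds,
    )))

    summary = {
        "pattern": code,
        "standard": standard,
        "n_tumors": report.n_tumors,
        "n_arms": report.n_arms,
        "n_animals": report.n_animals,
        "analyses": {
            "statistics": do_stats,
            "tgi": do_tgi,
            "response_labeling": True,
        },
        "artifacts": sorted(artifacts),
        "warnings": [m for _, _, m in report.warnings],
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    summary["artifacts"].append(str(out_dir / "summary.json"))
    return summary
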