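"""Human-readable run summary: cohort table, boxplots, staging histogram."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["render_report"]

_REQUIRED = ("subject_stats.csv", "cohort_summary.csv", "cohort_tests.csv", "cohort_auc.csv")


def render_report(run_dir) -> Path:
    """Write ``report.md`` (plus figures) summarizing a completed run.

    The table mirrors the cohort-summary layout (one row per MRE metric,
    group mean with interindividual SD in parentheses, CV rounded to whole
    percent). An empty cohort yields a graceful "no subjects" report.
    """
    run_dir = Path(run_dir)
    for name in _REQUIRED:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"incomplete run directory: missing {name}")
    subjects = pd.read_csv(run_dir / "subject_stats.csv")
    out = run_dir / "report.md"
    if subjects.empty:
        out.write_text("# Cohort report\n\nNo subjects in this run.\n")
        return out

    summary = pd.read_csv(run_dir / "cohort_summary.csv")
    tests = pd.read_csv(run_dir / "cohort_tests.csv")
    auc = pd.read_csv(run_dir / "cohort_auc.csv")

    def fmt(metric: str, mean: float, sd: float) -> str:
        digits = 0 if "CV" in metric else 2
        return f"{mean:.{digits}f} ({sd:.{digits}f})"

    lines = ["# Cohort report", "", "## MRE parameters by group", ""]
    lines.append("| Metric | All | PSC | Viral hepatitis | P |")
    lines.append("|---|---|---|---|---|")
    for _, row in summary.iterrows():
        m = row["metric"]
        p = tests.loc[tests["metric"] == m, "p"]
        p_txt = f"{float(p.iloc[0]):.3f}" if len(p) else ""
        lines.append(
            f"| {m} | {fmt(m, row['all_mean'], row['all_sd'])} "
            f"| {fmt(m, row['PSC_mean'], row['PSC_sd'])} "
            f"| {fmt(m, row['viral_mean'], row['viral_sd'])} | {p_txt} |"
        )
    lines += ["", "## Diagnostic performance (PSC vs viral)", ""]
    for _, row in auc.iterrows():
        lines.append(
            f"- {row['metric']}: AUC {row['auc']:.2f} "
            f"(95% CI {row['ci_lo']:.2f}-{row['ci_hi']:.2f})"
        )
    stage_counts = subjects["stage"].value_counts().sort_index()
    lines += ["", "## Fibrosis stage distribution", ""]
    for s, n in stage_counts.items():
        lines.append(f"- F{int(s)}: {int(n)}")
    lines.append("")
    out.write_text("\n".join(lines))

    _figures(subjects, run_dir)
    return out


def _figures(subjects: pd.DataFrame, run_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, col, label in (
        (axes[0], "sws_mean", "SWS (m/s)"),
        (axes[1], "sws_cv", "CV of SWS (%)"),
    ):
        data = [
            subjects.loc[subjects["group"] == g, col] for g in ("PSC", "viral")
        ]
        ax.boxplot(data, tick_labels=["PSC", "viral"])
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(run_dir / "boxplots.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(subjects["stage"], bins=[-0.5, 0.5, 1.5, 2.5, 3.5, 4.5], rwidth=0.8)
    ax.set_xlabel("fibrosis stage")
    ax.set_ylabel("subjects")
    fig.tight_layout()
    fig.savefig(run_dir / "stage_histogram.png", dpi=110)
    plt.close(fig)
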