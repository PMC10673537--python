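"""DIPA reports and figures.

A report bundles the per-period summaries with the boundaries and
conversion-table version that produced them.  Two figures mirror the
method's visual outputs: the longitudinal DIPA graph (stacked class-share
bars with efficiency-score and mean-MME traces) and the per-class MME
box-whisker plot with mean markers and 1.5xIQR outliers.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classification import ClassBoundaries, OPERATIONAL_BOUNDARIES
from .errors import ValidationError
from .mme import ConversionTable, load_conversion_table
from .scoring import (
    PERIODS,
    PatientVisit,
    PeriodSummary,
    annotate_visits,
    summarize_cohort,
)

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "DIPAReport",
    "build_report",
    "write_report_json",
    "read_report_json",
    "write_report_csv",
    "render_dipa_graph",
    "render_class_boxplot",
]

REPORT_SCHEMA_VERSION = "1"

_PERIOD_RANK = {p: i for i, p in enumerate(PERIODS)}

_CLASS_COLORS = {
    "A": "#4daf4a", "B": "#a6d854", "C": "#ffd92f", "D": "#fc8d62", "E": "#e41a1c",
}


@dataclass(frozen=True)
class DIPAReport:
    """Per-period summaries plus full provenance metadata."""

    summaries: tuple[PeriodSummary, ...]
    boundaries: ClassBoundaries
    table_version: str
    seed: int | None = None
    timestamp: str | None = None
    input_hash: str | None = None
    schema_version: str = REPORT_SCHEMA_VERSION

    def __post_init__(self) -> None:
        ranks = [_PERIOD_RANK[s.period] for s in self.summaries]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValidationError("report periods must be unique and in order")


def build_report(
    visits: Iterable[PatientVisit],
    table: ConversionTable | None = None,
    boundaries: ClassBoundaries = OPERATIONAL_BOUNDARIES,
    seed: int | None = None,
    input_hash: str | None = None,
    annotate: bool = True,
) -> DIPAReport:
    """Run the scoring pipeline and assemble a report."""
    if table is None:
        table = load_conversion_table()
    visits = list(visits)
    if annotate:
        visits = annotate_visits(visits, table, boundaries)
    summaries = tuple(summarize_cohort(visits))
    if not summaries:
        raise ValidationError("no visits to report on")
    return DIPAReport(
        summaries=summaries,
        boundaries=boundaries,
        table_version=table.version,
        seed=seed,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        input_hash=input_hash,
    )


def _summary_to_dict(s: PeriodSummary) -> dict:
    return {
        "period": s.period,
        "n": s.n,
        "efficiency_score": s.efficiency_score,
        "pct_on_narcotics": s.pct_on_narcotics,
        "mean_mme": s.mean_mme,
        "mean_mme_narcotics_only": s.mean_mme_narcotics_only,
        "class_distribution": dict(s.class_distribution),
        "ipa_by_class": {c: dict(v) for c, v in s.ipa_by_class.items()},
    }


def write_report_json(report: DIPAReport, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": report.schema_version,
        "table_version": report.table_version,
        "boundaries": json.loads(report.boundaries.to_json()),
        "seed": report.seed,
        "timestamp": report.timestamp,
        "input_hash": report.input_hash,
        "summaries": [_summary_to_dict(s) for s in report.summaries],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_report_json(path: str | Path) -> DIPAReport:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    summaries = tuple(
        PeriodSummary(
            period=s["period"],
            n=s["n"],
            efficiency_score=s["efficiency_score"],
            pct_on_narcotics=s["pct_on_narcotics"],
            mean_mme=s["mean_mme"],
            mean_mme_narcotics_only=s["mean_mme_narcotics_only"],
            class_distribution=s["class_distribution"],
            ipa_by_class={c: {int(k): v for k, v in d.items()}
                          for c, d in s["ipa_by_class"].items()},
        )
        for s in payload["summaries"]
    )
    return DIPAReport(
        summaries=summaries,
        boundaries=ClassBoundaries(**payload["boundaries"]),
        table_version=payload["table_version"],
        seed=payload.get("seed"),
        timestamp=payload.get("timestamp"),
        input_hash=payload.get("input_hash"),
        schema_version=payload.get("schema_version", REPORT_SCHEMA_VERSION),
    )


def write_report_csv(report: DIPAReport, path: str | Path) -> Path:
    """One CSV row per period: period,n,efficiency,pct_narcotics,mean_mme,pA..pE."""
    import csv

    path = Path(path)
    rows = [s.as_row() for s in report.summaries]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    return path


def render_dipa_graph(report: DIPAReport, out: str | Path) -> Path:
    """Render the longitudinal DIPA graph.

    Stacked bars show each period's class shares; a line gives the
    efficiency score (%); mean daily MME is traced on a secondary axis.
    """
    if not report.summaries:
        raise ValidationError("cannot render an empty report")
    out = Path(out)
    periods = [s.period for s in report.summaries]
    x = np.arange(len(periods))

    fig, ax = plt.subplots(figsize=(8, 5))
    bottom = np.zeros(len(periods))
    for letter in "ABCDE":
        shares = np.array(
            [100 * s.class_distribution.get(letter, 0.0) for s in report.summaries]
        )
        ax.bar(x, shares, bottom=bottom, width=0.6,
               color=_CLASS_COLORS[letter], label=f"class {letter}")
        bottom += shares

    eff = [s.efficiency_score for s in report.summaries]
    ax.plot(x, eff, "ko-", linewidth=2, label="efficiency score (%)")
    for xi, e in zip(x, eff):
        if np.isfinite(e):
            ax.annotate(f"{e:.1f}%", (xi, e), textcoords="offset points",
                        xytext=(0, 8), ha="center", fontsize=9)

    ax2 = ax.twinx()
    mmes = [s.mean_mme for s in report.summaries]
    ax2.plot(x, mmes, "b^--", label="mean daily MME")
    ax2.set_ylabel("mean daily MME", color="b")

    ax.set_xticks(x)
    ax.set_xticklabels(periods)
    ax.set_ylabel("share of responses (%)")
    ax.set_xlabel("post-operative period")
    ax.set_ylim(0, 115)
    ax.set_title("DIPA longitudinal report")
    handles, labels = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(handles + h2, labels + l2, loc="upper right", fontsize=8, ncols=2)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out


def render_class_boxplot(
    mmes_by_class: Mapping[str, Sequence[float]], out: str | Path
) -> Path:
    """Box-whisker of daily MME per narcotic class, mean marked 'x',
    points beyond 1.5xIQR drawn as 'o' outliers."""
    filled = {c: list(v) for c, v in mmes_by_class.items() if len(v) > 0}
    if not filled:
        raise ValidationError("all classes empty; nothing to plot")
    out = Path(out)
    letters = sorted(filled)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.boxplot(
        [filled[c] for c in letters],
        tick_labels=letters,
        showmeans=True,
        meanprops={"marker": "x", "markeredgecolor": "black"},
        flierprops={"marker": "o", "markerfacecolor": "none"},
        whis=1.5,
    )
    ax.set_xlabel("medication class")
    ax.set_ylabel("daily MME")
    ax.set_title("Daily MME by medication class")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out
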