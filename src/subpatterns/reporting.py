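"""Plot and table generation for a completed analysis run.

One run produces exactly eleven plots (PDF) and two tabular reports. The
plot set covers, in order: per-site transitions and transversions split by
codon position (1-2), the distribution of each directed change type per
codon position (3), synonymous and nonsynonymous events per site (4-5),
sliding-window category means, dS/dN and dN/dS (6-8), and the cumulative
curves including the running total Kt (9-11). Windows where dS = 0 appear
as gaps in the dN/dS plot, never as infinities.

Tables are views over the event list: every number in them is recomputable
from the events alone. Report 1 collects the plotted series plus both
normalizations of the substitution matrix; report 2 collects the tree-side
data (per-branch annotations and the full event list). The default format
is CSV — each report is a single file whose sections are delimited by
``## <section>`` comment lines — with a two-workbook XLSX writer behind a
flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import CATEGORIES, SubstitutionEvent
from .errors import EmptyInputError
from .markov_matrix import SubstitutionMatrix, conditional_probabilities
from .site_profiles import (
    CumulativeSeries,
    SiteProfile,
    WindowSeries,
)
from .tree_annotation import BranchAnnotation, branch_table

PLOT_MANIFEST: dict[str, str] = {
    "plot01_ts_per_site_by_position":
        "Transitions at each site, one panel per codon position",
    "plot02_tv_per_site_by_position":
        "Transversions at each site, one panel per codon position",
    "plot03_change_types_by_position":
        "Count of each directed base change per codon position",
    "plot04_synonymous_per_site":
        "Synonymous transitions (As) and transversions (Bs) per site",
    "plot05_nonsynonymous_per_site":
        "Nonsynonymous transitions (Aa) and transversions (Ba) per site",
    "plot06_windowed_categories":
        "Sliding-window means of As, Bs, Aa, Ba",
    "plot07_windowed_ds_dn":
        "Sliding-window dS (As+Bs) and dN (Aa+Ba)",
    "plot08_windowed_dn_ds":
        "Sliding-window dN/dS ratio (gaps where dS = 0)",
    "plot09_cumulative_synonymous":
        "Cumulative As and Bs along the sequence",
    "plot10_cumulative_nonsynonymous":
        "Cumulative Aa and Ba along the sequence",
    "plot11_cumulative_total":
        "Cumulative total substitutions (Kt) along the sequence",
}


@dataclass
class ReportBundle:
    """File inventory of one run's plots and tables."""

    plot_files: list[Path] = field(default_factory=list)
    table_files: list[Path] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)


def _per_position_panels(fig_title, sites, values, positions, ylabel):
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6))
    for pos, ax in zip((1, 2, 3), axes):
        mask = positions == pos
        ax.vlines(sites[mask], 0, values[mask], lw=0.8)
        ax.set_ylabel(f"pos {pos}")
    axes[0].set_title(fig_title)
    axes[-1].set_xlabel("nucleotide site")
    fig.supylabel(ylabel)
    return fig


def render_plots(
    profile: SiteProfile,
    windows: WindowSeries,
    cumulative: CumulativeSeries,
    matrix: SubstitutionMatrix,
    annotations: Iterable[BranchAnnotation],
    out_dir: str | Path,
) -> ReportBundle:
    """Write the eleven PDF plots plus a JSON manifest.

    A run with zero events still yields eleven plots with all-zero series;
    only a missing profile is an error.
    """
    if profile is None:
        raise EmptyInputError("no site profile to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(manifest=dict(PLOT_MANIFEST))

    sites = np.arange(1, profile.length + 1)
    positions = (sites - 1) % 3 + 1

    def save(fig, name):
        path = out_dir / f"{name}.pdf"
        fig.savefig(path, format="pdf")
        plt.close(fig)
        bundle.plot_files.append(path)

    save(_per_position_panels("Transitions per site", sites, profile.ts,
                              positions, "Ts count"),
         "plot01_ts_per_site_by_position")
    save(_per_position_panels("Transversions per site", sites, profile.tv,
                              positions, "Tv count"),
         "plot02_tv_per_site_by_position")

    fig, ax = plt.subplots(figsize=(9, 4))
    profile.type_by_position.plot.bar(ax=ax)
    ax.set_xlabel("substitution type")
    ax.set_ylabel("count")
    ax.set_title("Substitution types per codon position")
    ax.legend(title="codon position")
    fig.tight_layout()
    save(fig, "plot03_change_types_by_position")

    for name, cats, title in (
        ("plot04_synonymous_per_site", ("As", "Bs"),
         "Synonymous substitutions per site"),
        ("plot05_nonsynonymous_per_site", ("Aa", "Ba"),
         "Nonsynonymous substitutions per site"),
    ):
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
        for cat, ax in zip(cats, axes):
            ax.vlines(sites, 0, profile.counts[cat], lw=0.8)
            ax.set_ylabel(cat)
        axes[0].set_title(title)
        axes[-1].set_xlabel("nucleotide site")
        save(fig, name)

    centers = windows.window_starts + (windows.window - 1) / 2

    fig, ax = plt.subplots(figsize=(8, 4))
    for cat in CATEGORIES:
        ax.plot(centers, windows.means[cat], label=cat)
    ax.set_xlabel("window center (nt)")
    ax.set_ylabel("mean substitutions per site")
    ax.set_title(f"Sliding window ({windows.window} nt / step {windows.step})")
    ax.legend()
    save(fig, "plot06_windowed_categories")

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(centers, windows.ds, label="dS = As+Bs")
    ax.plot(centers, windows.dn, label="dN = Aa+Ba")
    ax.set_xlabel("window center (nt)")
    ax.set_ylabel("mean substitutions per site")
    ax.set_title("Windowed synonymous and nonsynonymous totals")
    ax.legend()
    save(fig, "plot07_windowed_ds_dn")

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(centers, windows.ratio)  # NaN renders as gaps
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("window center (nt)")
    ax.set_ylabel("dN/dS")
    ax.set_title("Windowed dN/dS (gaps where dS = 0)")
    save(fig, "plot08_windowed_dn_ds")

    for name, cats, title in (
        ("plot09_cumulative_synonymous", ("As", "Bs"),
         "Cumulative synonymous substitutions"),
        ("plot10_cumulative_nonsynonymous", ("Aa", "Ba"),
         "Cumulative nonsynonymous substitutions"),
    ):
        fig, ax = plt.subplots(figsize=(8, 4))
        for cat in cats:
            ax.plot(cumulative.positions, cumulative.totals[cat],
                    drawstyle="steps-post", label=cat)
        ax.set_xlabel("nucleotide position")
        ax.set_ylabel("cumulative count")
        ax.set_title(title)
        ax.legend()
        save(fig, name)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(cumulative.positions, cumulative.kt, drawstyle="steps-post")
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel("Kt")
    ax.set_title("Cumulative total substitutions (Kt)")
    save(fig, "plot11_cumulative_total")

    with open(out_dir / "plot_manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
    return bundle


def _events_frame(events: list[SubstitutionEvent]) -> pd.DataFrame:
    rows = [
        {
            "parent": ev.branch[0], "child": ev.branch[1], "site": ev.site,
            "codon_index": ev.codon_index,
            "codon_position": ev.codon_position,
            "from_base": ev.from_base, "to_base": ev.to_base,
            "from_codon": ev.from_codon, "to_codon": ev.to_codon,
            "class": ev.mutation_class, "effect": ev.effect,
            "category": ev.category, "posterior": ev.posterior,
        }
        for ev in events
    ]
    return pd.DataFrame(rows)


def _report_sections_plot_data(profile, windows, cumulative, matrix):
    if matrix.conditional is None:
        matrix = conditional_probabilities(matrix)
    return {
        "per_site": profile.to_frame(),
        "type_by_position": profile.type_by_position.reset_index(
            names="change"),
        "windowed": windows.to_frame(),
        "cumulative": cumulative.to_frame(),
        "matrix_counts": matrix.counts_frame().reset_index(names="from"),
        "matrix_conditional": matrix.conditional_frame().reset_index(
            names="from"),
        "matrix_joint": matrix.joint_frame().reset_index(names="from"),
    }


def _report_sections_tree_data(annotations, events):
    anns = list(annotations)
    return {
        "branch_annotations": branch_table(anns),
        "events": _events_frame(events),
    }


def _write_sectioned_csv(path: Path, sections: dict[str, pd.DataFrame]):
    with open(path, "w", newline="") as fh:
        for name, frame in sections.items():
            fh.write(f"## {name}\n")
            frame.to_csv(fh, index=False)
            fh.write("\n")


def _write_xlsx(path: Path, sections: dict[str, pd.DataFrame]):
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, frame in sections.items():
            frame.to_excel(writer, sheet_name=name[:31], index=False)


def export_tables(
    profile: SiteProfile,
    windows: WindowSeries,
    cumulative: CumulativeSeries,
    matrix: SubstitutionMatrix,
    annotations: Iterable[BranchAnnotation],
    events: list[SubstitutionEvent],
    out_dir: str | Path,
    fmt: str = "csv",
) -> ReportBundle:
    """Write the two tabular reports (plot data and tree data)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections1 = _report_sections_plot_data(profile, windows, cumulative,
                                           matrix)
    sections2 = _report_sections_tree_data(annotations, events)
    bundle = ReportBundle()
    ext = "xlsx" if fmt == "xlsx" else "csv"
    writer = _write_xlsx if fmt == "xlsx" else _write_sectioned_csv
    for stem, sections in (("report1_plot_data", sections1),
                           ("report2_tree_data", sections2)):
        path = out_dir / f"{stem}.{ext}"
        writer(path, sections)
        bundle.table_files.append(path)
    return bundle
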