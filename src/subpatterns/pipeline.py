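"""End-to-end analysis: parse -> classify -> profile -> matrix -> trees.

This is the library face of the command line's ``analyze``: everything the
reports contain is computed here once and handed to :mod:`reporting`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import reporting
from .classify import SubstitutionEvent, build_events
from .markov_matrix import (
    SubstitutionMatrix,
    conditional_probabilities,
    count_matrix,
)
from .rst_io import RstDocument, parse_rst
from .site_profiles import (
    CumulativeSeries,
    SiteProfile,
    WindowSeries,
    cumulative_series,
    site_counts,
    sliding_windows,
)
from .tree_annotation import BranchAnnotation, annotate_branches, export_trees


@dataclass
class AnalysisResult:
    """Everything computed from one reconstruction file."""

    document: RstDocument
    events: list[SubstitutionEvent]
    profile: SiteProfile
    windows: WindowSeries
    cumulative: CumulativeSeries
    matrix: SubstitutionMatrix
    annotations: list[BranchAnnotation]
    tree_aa_newick: str
    tree_nt_newick: str


def analyze_document(
    doc: RstDocument,
    window: int = 90,
    step: int = 9,
    min_posterior: float = 0.0,
) -> AnalysisResult:
    """Run the full pipeline on a parsed document."""
    events = build_events(doc, min_posterior=min_posterior)
    profile = site_counts(events, doc.alignment_length)
    window = min(window, doc.alignment_length)
    windows = sliding_windows(profile, window=window, step=step)
    cumulative = cumulative_series(profile, step=step)
    matrix = conditional_probabilities(count_matrix(events))
    annotations = annotate_branches(events, doc.tree)
    tree_aa, tree_nt = export_trees(annotations, doc.tree)
    return AnalysisResult(
        document=doc,
        events=events,
        profile=profile,
        windows=windows,
        cumulative=cumulative,
        matrix=matrix,
        annotations=annotations,
        tree_aa_newick=tree_aa,
        tree_nt_newick=tree_nt,
    )


def analyze_rst_text(rst_text: str, **kwargs) -> AnalysisResult:
    return analyze_document(parse_rst(rst_text), **kwargs)


def write_outputs(
    result: AnalysisResult,
    out_dir: str | Path,
    fmt: str = "csv",
) -> reporting.ReportBundle:
    """Write plots, tables and both annotated trees to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = reporting.render_plots(
        result.profile, result.windows, result.cumulative, result.matrix,
        result.annotations, out_dir,
    )
    tables = reporting.export_tables(
        result.profile, result.windows, result.cumulative, result.matrix,
        result.annotations, result.events, out_dir, fmt=fmt,
    )
    bundle.table_files = tables.table_files
    (out_dir / "tree_aa_changes.nwk").write_text(result.tree_aa_newick)
    (out_dir / "tree_nonsyn_nt_changes.nwk").write_text(result.tree_nt_newick)
    return bundle
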