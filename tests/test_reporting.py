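"""Report contract: eleven plots, two tables, tables as views of events."""

import numpy as np
import pandas as pd
import pytest

from subpatterns import (
    analyze_document,
    parse_rst,
    simulate,
    write_outputs,
    write_rst,
)
from subpatterns.reporting import PLOT_MANIFEST


@pytest.fixture(scope="module")
def result(oracle_doc):
    return analyze_document(oracle_doc, window=90, step=9)


def test_run_produces_eleven_plots_two_tables_two_trees(result, tmp_path):
    bundle = write_outputs(result, tmp_path)
    assert len(bundle.plot_files) == 11
    assert all(p.suffix == ".pdf" and p.stat().st_size > 0
               for p in bundle.plot_files)
    assert len(bundle.table_files) == 2
    assert len(bundle.manifest) == 11
    assert set(bundle.manifest) == set(PLOT_MANIFEST)
    assert (tmp_path / "tree_aa_changes.nwk").exists()
    assert (tmp_path / "tree_nonsyn_nt_changes.nwk").exists()


def test_zero_event_run_still_renders_everything(tmp_path):
    log = simulate(n_tips=4, length_codons=40, events_per_branch=0, seed=0)
    result = analyze_document(parse_rst(write_rst(log)), window=30, step=3)
    bundle = write_outputs(result, tmp_path)
    assert len(bundle.plot_files) == 11
    assert len(bundle.table_files) == 2
    assert result.profile.total_events == 0


def _read_sections(path):
    """Split a sectioned CSV report back into named DataFrames."""
    sections = {}
    current_name, current_lines = None, []
    for line in path.read_text().splitlines():
        if line.startswith("## "):
            if current_name and current_lines:
                sections[current_name] = current_lines
            current_name, current_lines = line[3:], []
        elif line.strip():
            current_lines.append(line)
    if current_name and current_lines:
        sections[current_name] = current_lines
    import io

    return {
        name: pd.read_csv(io.StringIO("\n".join(lines)))
        for name, lines in sections.items()
    }


def test_csv_report_sections_are_views_of_the_event_list(result, tmp_path):
    bundle = write_outputs(result, tmp_path)
    report1 = _read_sections(bundle.table_files[0])
    report2 = _read_sections(bundle.table_files[1])

    assert len(report2["events"]) == len(result.events)
    total = len(result.events)
    per_site = report1["per_site"]
    assert per_site[["As", "Bs", "Aa", "Ba"]].values.sum() == total
    cond = report1["matrix_conditional"].set_index("from")
    row_sums = cond.sum(axis=1)
    counts = report1["matrix_counts"].set_index("from")
    populated = counts.sum(axis=1) > 0
    assert np.allclose(row_sums[populated], 1.0)
    assert report1["matrix_counts"].set_index("from").values.sum() == total
    assert report1["cumulative"]["Kt"].iloc[-1] == total
    n_branch_events = report2["branch_annotations"]["n_events"].sum()
    assert n_branch_events == total


def test_dnds_gaps_export_as_empty_cells_never_infinite(tmp_path):
    # all-nonsynonymous history is unlikely; force dS = 0 via tiny run with
    # the synonymous columns zeroed is not honest -- instead check exported
    # ratio column of a real run has no +/-inf and NaN where dS == 0
    log = simulate(n_tips=4, length_codons=60, events_per_branch=2, seed=21)
    result = analyze_document(parse_rst(write_rst(log)), window=9, step=9)
    bundle = write_outputs(result, tmp_path)
    windowed = _read_sections(bundle.table_files[0])["windowed"]
    assert not np.isinf(windowed["dN/dS"].to_numpy()).any()
    zero_ds = windowed["dS"] == 0
    assert windowed.loc[zero_ds, "dN/dS"].isna().all()


def test_xlsx_reports_round_trip(result, tmp_path):
    from subpatterns.reporting import export_tables

    bundle = export_tables(
        result.profile, result.windows, result.cumulative, result.matrix,
        result.annotations, result.events, tmp_path, fmt="xlsx",
    )
    assert len(bundle.table_files) == 2
    sheets = pd.read_excel(bundle.table_files[0], sheet_name=None)
    assert "matrix_conditional" in sheets
    events = pd.read_excel(bundle.table_files[1], sheet_name="events")
    assert len(events) == len(result.events)


def test_regeneration_from_exported_events_is_bit_identical(result, tmp_path):
    """Tables are views: recomputing from the exported event list rebuilds
    the same reports byte for byte."""
    from subpatterns.classify import SubstitutionEvent
    from subpatterns.markov_matrix import (
        conditional_probabilities, count_matrix,
    )
    from subpatterns.reporting import export_tables
    from subpatterns.site_profiles import (
        cumulative_series, site_counts, sliding_windows,
    )
    from subpatterns.tree_annotation import annotate_branches

    first = write_outputs(result, tmp_path / "a")
    events_table = _read_sections(first.table_files[1])["events"]
    rebuilt_events = [
        SubstitutionEvent(
            branch=(int(r.parent), int(r.child)), site=int(r.site),
            codon_index=int(r.codon_index),
            codon_position=int(r.codon_position),
            from_base=r.from_base, to_base=r.to_base,
            from_codon=r.from_codon, to_codon=r.to_codon,
            mutation_class=r["class"], effect=r.effect, category=r.category,
            posterior=float(r.posterior),
        )
        for _, r in events_table.iterrows()
    ]
    length = result.document.alignment_length
    profile = site_counts(rebuilt_events, length)
    windows = sliding_windows(profile, window=90, step=9)
    cumulative = cumulative_series(profile, step=9)
    matrix = conditional_probabilities(count_matrix(rebuilt_events))
    annotations = annotate_branches(rebuilt_events, result.document.tree)
    second = export_tables(profile, windows, cumulative, matrix,
                           annotations, rebuilt_events, tmp_path / "b")
    for one, two in zip(first.table_files, second.table_files):
        assert one.read_bytes() == two.read_bytes()
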