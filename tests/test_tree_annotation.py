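"""Branch annotation strings, highlighting and the two exported trees."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subpatterns import (
    annotate_branches,
    at_least,
    build_events,
    export_trees,
    format_annotation,
    highlight,
    parse_annotation,
    read_annotated_newick,
)
from subpatterns.errors import (
    AnnotationSyntaxError,
    EmptyAnnotationError,
    UnknownBranchError,
)
from subpatterns.tree_annotation import CELLS, BranchAnnotation


def test_format_annotation_worked_example():
    ann = BranchAnnotation(
        branch=(20, 18), seq_index=18,
        counts={("Ts", 1): 1, ("Ts", 2): 3, ("Tv", 1): 2},
    )
    assert format_annotation(ann) == "18_1@Ts1_3@Ts2_2@Tv1"


def test_parse_annotation_worked_example():
    seq_index, counts = parse_annotation("18_1@Ts1_3@Ts2_2@Tv1")
    assert seq_index == 18
    assert counts == {("Ts", 1): 1, ("Ts", 2): 3, ("Tv", 1): 2}
    assert counts[("Ts", 2)] == 3


def test_single_segment_annotation():
    ann = BranchAnnotation(branch=(9, 4), seq_index=4,
                           counts={("Tv", 3): 1})
    assert format_annotation(ann) == "4_1@Tv3"


@pytest.mark.parametrize("bad", ["18_@Ts1", "18", "_1@Ts1", "18_1@Tx1",
                                 "18_1@Ts4", "18_0@Ts1",
                                 "18_1@Ts1_2@Ts1"])
def test_parse_annotation_rejects_bad_strings(bad):
    with pytest.raises(AnnotationSyntaxError):
        parse_annotation(bad)


def test_empty_annotation_cannot_be_formatted():
    with pytest.raises(EmptyAnnotationError):
        format_annotation(BranchAnnotation(branch=(9, 4), seq_index=4))


@settings(deadline=None, max_examples=1000, derandomize=True)
@given(
    seq_index=st.integers(min_value=1, max_value=9999),
    counts=st.dictionaries(
        st.sampled_from(CELLS), st.integers(min_value=1, max_value=99),
        min_size=1, max_size=6,
    ),
)
def test_format_parse_round_trip(seq_index, counts):
    ann = BranchAnnotation(branch=(0, seq_index), seq_index=seq_index,
                           counts=dict(counts))
    text = format_annotation(ann)
    assert parse_annotation(text) == (seq_index, counts)


def test_annotate_branches_matches_ground_truth(oracle_log, oracle_doc):
    events = build_events(oracle_doc)
    annotations = annotate_branches(events, oracle_doc.tree)
    truth = oracle_log.branch_totals()
    got = {ann.branch: ann.total for ann in annotations}
    assert got == {b: n for b, n in truth.items() if n > 0}
    assert sum(ann.total for ann in annotations) == len(events)
    for ann in annotations:
        assert ann.seq_index == ann.branch[1]
        assert len(ann.aa_changes) == len(ann.nonsyn_nt_changes)
        n_nonsyn = sum(1 for ev in events
                       if ev.branch == ann.branch
                       and ev.effect == "nonsynonymous")
        assert len(ann.aa_changes) == n_nonsyn


def test_annotate_branches_rejects_unknown_branch(oracle_doc):
    events = build_events(oracle_doc)
    bad = events[0].__class__(**{**events[0].__dict__, "branch": (998, 999)})
    with pytest.raises(UnknownBranchError):
        annotate_branches([bad], oracle_doc.tree)


def test_no_events_yield_no_annotations(oracle_doc):
    assert annotate_branches([], oracle_doc.tree) == []


def test_highlight_criteria(oracle_doc):
    events = build_events(oracle_doc)
    annotations = annotate_branches(events, oracle_doc.tree)
    everything = highlight(annotations, lambda counts: True)
    assert everything == {ann.branch for ann in annotations}
    assert highlight(annotations, at_least("Ts", 2, 10 ** 9)) == set()
    ts2 = highlight(annotations, at_least("Ts", 2))
    expected = {ann.branch for ann in annotations
                if ann.counts.get(("Ts", 2), 0) >= 1}
    assert ts2 == expected


def test_exported_trees_carry_every_aa_change_once(oracle_doc):
    events = build_events(oracle_doc)
    annotations = annotate_branches(events, oracle_doc.tree)
    tree_aa, tree_nt = export_trees(annotations, oracle_doc.tree)

    _, aa_labels = read_annotated_newick(tree_aa, annotation_name="aa_subs")
    _, nt_labels = read_annotated_newick(tree_nt, annotation_name="nt_subs")
    from collections import Counter

    exported = Counter(
        change for label in aa_labels.values() for change in label.split(";")
    )
    truth = Counter(
        f"{ev.from_aa}{ev.codon_index}{ev.to_aa}"
        for ev in events if ev.effect == "nonsynonymous"
    )
    assert exported == truth
    exported_nt = Counter(
        change for label in nt_labels.values() for change in label.split(";")
    )
    truth_nt = Counter(
        f"{ev.from_base.lower()}{ev.site}{ev.to_base.lower()}"
        for ev in events if ev.effect == "nonsynonymous"
    )
    assert exported_nt == truth_nt


def test_tree_without_nonsyn_events_has_unlabeled_nt_tree(oracle_doc):
    annotations = annotate_branches([], oracle_doc.tree)
    tree_aa, tree_nt = export_trees(annotations, oracle_doc.tree)
    assert "[&" not in tree_aa and "[&" not in tree_nt
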