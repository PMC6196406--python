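"""Per-branch annotation of a phylogeny with classified substitutions.

Each branch bearing events gets a :class:`BranchAnnotation` summarizing its
transition/transversion counts per codon position, plus the amino-acid and
nucleotide change lists for its nonsynonymous events. The compact string
form follows the ``18_1@Ts1_3@Ts2_2@Tv1`` grammar: sequence number 18 has
one transition at codon position 1, three transitions at position 2 and two
transversions at position 1. Segments are ordered Ts before Tv, positions
ascending, zero-count cells omitted.

Conventions for the change lists (the string grammar constrains neither):
amino-acid changes are ``<fromAA><codon_index><toAA>`` (e.g. ``L45P``) with
a 1-based codon index; nucleotide changes are lower case
``<from><site><to>`` (e.g. ``a263t``) with a 1-based nucleotide site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .classify import SubstitutionEvent
from .errors import (
    AnnotationSyntaxError,
    EmptyAnnotationError,
    UnknownBranchError,
)
from .genetic_code import translate
from .trees import Branch, TreeTopology, write_annotated_newick

#: (class, position) cells in canonical output order.
CELLS = tuple(
    (cls, pos) for cls in ("Ts", "Tv") for pos in (1, 2, 3)
)

_SEGMENT = re.compile(r"^(\d+)@(Ts|Tv)([123])$")
_ANNOTATION = re.compile(r"^(\d+)((?:_\d+@(?:Ts|Tv)[123])+)$")


@dataclass
class BranchAnnotation:
    """Summary of all events on one (parent, child) branch."""

    branch: Branch
    seq_index: int  # child node number (tip index for external branches)
    counts: dict[tuple[str, int], int] = field(default_factory=dict)
    aa_changes: list[str] = field(default_factory=list)
    nonsyn_nt_changes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def annotate_branches(
    events: Iterable[SubstitutionEvent], tree: TreeTopology
) -> list[BranchAnnotation]:
    """Build one annotation per branch bearing at least one event.

    Internal and external branches are treated alike; ``seq_index`` is the
    child node's rst number, which for external branches is the tip's
    sequence number in the alignment.
    """
    edges = set(tree.branches)
    by_branch: dict[Branch, BranchAnnotation] = {}
    for ev in events:
        if ev.branch not in edges:
            raise UnknownBranchError(f"event on unknown branch {ev.branch}")
        ann = by_branch.get(ev.branch)
        if ann is None:
            ann = BranchAnnotation(branch=ev.branch, seq_index=ev.branch[1])
            by_branch[ev.branch] = ann
        key = (ev.mutation_class, ev.codon_position)
        ann.counts[key] = ann.counts.get(key, 0) + 1
        if ev.effect == "nonsynonymous":
            ann.aa_changes.append(
                f"{translate(ev.from_codon)}{ev.codon_index}"
                f"{translate(ev.to_codon)}"
            )
            ann.nonsyn_nt_changes.append(
                f"{ev.from_base.lower()}{ev.site}{ev.to_base.lower()}"
            )
    return [by_branch[b] for b in sorted(by_branch)]


def format_annotation(annotation: BranchAnnotation) -> str:
    """Render the compact count string, e.g. ``18_1@Ts1_3@Ts2_2@Tv1``."""
    segments = [
        f"{annotation.counts[cell]}@{cell[0]}{cell[1]}"
        for cell in CELLS
        if annotation.counts.get(cell, 0) > 0
    ]
    if not segments:
        raise EmptyAnnotationError(
            f"branch {annotation.branch} has no counted events"
        )
    return "_".join([str(annotation.seq_index)] + segments)


def parse_annotation(text: str) -> tuple[int, dict[tuple[str, int], int]]:
    """Parse a count string back into (seq_index, counts map)."""
    m = _ANNOTATION.match(text.strip())
    if not m:
        raise AnnotationSyntaxError(f"bad annotation string: {text!r}")
    seq_index = int(m.group(1))
    counts: dict[tuple[str, int], int] = {}
    for part in m.group(2).lstrip("_").split("_"):
        seg = _SEGMENT.match(part)
        count, cls, pos = seg.groups()
        key = (cls, int(pos))
        if key in counts:
            raise AnnotationSyntaxError(
                f"cell {cls}{pos} repeated in {text!r}"
            )
        counts[key] = int(count)
    if any(v == 0 for v in counts.values()):
        raise AnnotationSyntaxError(f"zero count segment in {text!r}")
    return seq_index, counts


def at_least(mutation_class: str, position: int, min_count: int = 1
             ) -> Callable[[dict[tuple[str, int], int]], bool]:
    """Criterion factory: at least ``min_count`` events of a given cell."""
    def criterion(counts: dict[tuple[str, int], int]) -> bool:
        return counts.get((mutation_class, position), 0) >= min_count
    return criterion


def highlight(
    annotations: Iterable[BranchAnnotation],
    criterion: Callable[[dict[tuple[str, int], int]], bool],
) -> set[Branch]:
    """Branches whose count map satisfies a criterion.

    Typical use: ``highlight(anns, at_least("Ts", 2))`` selects branches
    with transitions at the second codon position, the kind of query used
    to color tips in a tree viewer.
    """
    return {a.branch for a in annotations if criterion(a.counts)}


def export_trees(
    annotations: Iterable[BranchAnnotation], tree: TreeTopology
) -> tuple[str, str]:
    """Two annotated Newick strings: amino-acid and nucleotide changes.

    Tree A labels each branch with its inferred amino-acid changes, tree B
    with the corresponding nonsynonymous nucleotide changes; branches
    without nonsynonymous events carry no label. Both use FigTree-style
    bracket comments and round-trip through a Newick parser.
    """
    aa_labels: dict[Branch, str] = {}
    nt_labels: dict[Branch, str] = {}
    for ann in annotations:
        if ann.aa_changes:
            aa_labels[ann.branch] = ";".join(ann.aa_changes)
        if ann.nonsyn_nt_changes:
            nt_labels[ann.branch] = ";".join(ann.nonsyn_nt_changes)
    tree_aa = write_annotated_newick(tree, aa_labels, annotation_name="aa_subs")
    tree_nt = write_annotated_newick(tree, nt_labels, annotation_name="nt_subs")
    return tree_aa, tree_nt


def branch_table(annotations: Iterable[BranchAnnotation]):
    """Per-branch summary rows (used by reporting and the CLI)."""
    import pandas as pd

    rows = []
    for ann in annotations:
        row = {
            "parent": ann.branch[0],
            "child": ann.branch[1],
            "seq_index": ann.seq_index,
            "annotation": format_annotation(ann),
            "n_events": ann.total,
            "aa_changes": ";".join(ann.aa_changes),
            "nonsyn_nt_changes": ";".join(ann.nonsyn_nt_changes),
        }
        for cls, pos in CELLS:
            row[f"{cls}{pos}"] = ann.counts.get((cls, pos), 0)
        rows.append(row)
    return pd.DataFrame(rows)
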