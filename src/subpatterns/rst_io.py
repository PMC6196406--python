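"""Reading PAML ancestral-reconstruction (*rst*) files.

Supported dialect
-----------------
The parser targets the reconstruction report emitted by PAML 4.x baseml and
codeml runs with ancestral inference enabled, restricted to the subset of
that file the pipeline consumes:

* a header line ``Supplemental results for BASEML``/``CODEML``;
* a ``tree with node labels`` section holding one Newick tree whose tips
  are ``k_name`` and whose internal nodes carry bare numbers;
* a ``List of extant and reconstructed sequences`` section with a
  ``<n_nodes> <alignment_length>`` size line followed by ``node #k  SEQ``
  lines (whitespace inside sequences is ignored);
* a ``Summary of changes along branches`` section of ``Branch N: a..b``
  blocks whose change lines are either ``site base prob -> base`` (baseml)
  or ``site codon (aa) prob -> codon (aa)`` (codeml).

Sites are 1-based nucleotide positions throughout. Lines outside this
grammar are skipped with a logged warning so that cosmetic drift between
PAML versions does not abort a run; lines that *start* like a branch header
or change line but fail to parse raise :class:`MalformedBlockError`.

Input alignments must be protein-coding, gap-free and ambiguity-free; any
non-ACGT character in a sequence is a hard error.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import (
    FrameError,
    GapOrAmbiguityError,
    MalformedBlockError,
    UnrecognizedFormatError,
)
from .trees import (  # noqa: F401  (annotated-Newick writer re-exported here)
    TreeTopology,
    from_numbered_newick,
    read_annotated_newick,
    write_annotated_newick,
)

logger = logging.getLogger(__name__)

BASEML = "baseml"
CODEML = "codeml"

_HEADER = re.compile(r"Supplemental results for (BASEML|CODEML)", re.IGNORECASE)
_TREE_MARKER = "tree with node labels"
_SEQ_MARKER = "List of extant and reconstructed sequences"
_CHANGES_MARKER = "Summary of changes along branches"
_NODE_LINE = re.compile(r"^node\s+#(\d+)\s+(.*)$")
_BRANCH_HEADER = re.compile(
    r"^Branch\s+(\d+):\s+(\d+)\.\.(\d+)\s*(?:\(\s*(.*?)\s*\))?\s*$"
)
_BASEML_CHANGE = re.compile(
    r"^\s*(\d+)\s+([A-Z])\s+([01]?\.\d+|1\.0+|1)\s+->\s+([A-Z])\s*$"
)
_CODEML_CHANGE = re.compile(
    r"^\s*(\d+)\s+([A-Z]{3})\s+\((.)\)\s+([01]?\.\d+|1\.0+|1)\s+->\s+"
    r"([A-Z]{3})\s+\((.)\)\s*$"
)

_DNA = set("ACGT")


@dataclass(frozen=True)
class RawChange:
    """One inferred substitution line: 1-based nt site, states, posterior."""

    site: int
    from_state: str
    to_state: str
    from_aa: str = ""
    to_aa: str = ""
    posterior: float | None = None


@dataclass
class BranchRecord:
    parent: int
    child: int
    child_label: str = ""
    raw_changes: list[RawChange] = field(default_factory=list)


@dataclass
class RstDocument:
    """Structured contents of an rst file."""

    program_tag: str  # "baseml" | "codeml"
    alignment_length: int
    taxa: list[tuple[int, str]]
    tree: TreeTopology
    branches: list[BranchRecord]
    node_sequences: dict[int, str]

    @property
    def n_changes(self) -> int:
        return sum(len(b.raw_changes) for b in self.branches)


def detect_program(rst_text: str) -> str:
    """Identify which PAML program produced the file."""
    m = _HEADER.search(rst_text)
    if m:
        return m.group(1).lower()
    # fall back on the shape of change lines
    for line in rst_text.splitlines():
        if _CODEML_CHANGE.match(line):
            return CODEML
        if _BASEML_CHANGE.match(line):
            return BASEML
    raise UnrecognizedFormatError(
        "neither a baseml nor a codeml reconstruction header was found"
    )


def _validate_sequence(seq: str, node: int, lineno: int) -> str:
    bad = set(seq) - _DNA
    if bad:
        raise GapOrAmbiguityError(
            f"line {lineno}: sequence of node {node} contains "
            f"{sorted(bad)}; input must be gap-free and ambiguity-free DNA"
        )
    return seq


def parse_rst(rst_text: str) -> RstDocument:
    """Parse rst text into an :class:`RstDocument`.

    Raises :class:`GapOrAmbiguityError` on non-ACGT sequence characters,
    :class:`FrameError` for codeml alignments whose length is not a
    multiple of three, and :class:`MalformedBlockError` (with line number)
    for unparseable branch blocks.
    """
    program = detect_program(rst_text)
    lines = rst_text.splitlines()

    tree: TreeTopology | None = None
    node_sequences: dict[int, str] = {}
    branches: list[BranchRecord] = []
    alignment_length: int | None = None

    section = None
    current: BranchRecord | None = None
    expect_tree_line = False

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if _TREE_MARKER in line:
            expect_tree_line = True
            continue
        if _SEQ_MARKER in line:
            section = "sequences"
            continue
        if _CHANGES_MARKER in line:
            section = "changes"
            continue

        if expect_tree_line and stripped:
            if tree is None and stripped.endswith(";"):
                tree = from_numbered_newick(stripped)
            expect_tree_line = False
            continue

        if not stripped:
            continue

        if section == "sequences":
            m = _NODE_LINE.match(stripped)
            if m:
                node = int(m.group(1))
                seq = re.sub(r"\s+", "", m.group(2)).upper()
                node_sequences[node] = _validate_sequence(seq, node, lineno)
                continue
            size = re.match(r"^(\d+)\s+(\d+)$", stripped)
            if size:
                alignment_length = int(size.group(2))
                continue
            logger.warning("line %d: skipping unrecognized line in "
                           "sequence section: %r", lineno, stripped)
            continue

        if section == "changes":
            if stripped.startswith("Branch"):
                m = _BRANCH_HEADER.match(stripped)
                if not m:
                    raise MalformedBlockError(
                        f"unparseable branch header: {stripped!r}", lineno
                    )
                current = BranchRecord(
                    parent=int(m.group(2)),
                    child=int(m.group(3)),
                    child_label=m.group(4) or "",
                )
                branches.append(current)
                continue
            if re.match(r"^\d", stripped):
                change = _parse_change_line(stripped, program, lineno)
                if current is None:
                    raise MalformedBlockError(
                        "change line before any branch header", lineno
                    )
                current.raw_changes.append(change)
                continue
            if "Check root" in stripped:
                continue
            logger.warning("line %d: skipping unrecognized line in "
                           "changes section: %r", lineno, stripped)
            continue

    if tree is None:
        raise UnrecognizedFormatError("no numbered node tree found")
    if not node_sequences:
        raise UnrecognizedFormatError("no reconstructed sequences found")

    seq_lengths = {len(s) for s in node_sequences.values()}
    if len(seq_lengths) != 1:
        raise MalformedBlockError(
            f"node sequences have differing lengths: {sorted(seq_lengths)}"
        )
    (seq_len,) = seq_lengths
    if alignment_length is None:
        alignment_length = seq_len
    elif alignment_length != seq_len:
        raise MalformedBlockError(
            f"declared alignment length {alignment_length} != sequence "
            f"length {seq_len}"
        )
    if program == CODEML and alignment_length % 3 != 0:
        raise FrameError(
            f"codeml alignment length {alignment_length} is not a "
            "multiple of 3"
        )

    edges = set(tree.branches)
    for rec in branches:
        if (rec.parent, rec.child) not in edges:
            raise MalformedBlockError(
                f"branch {rec.parent}..{rec.child} is not an edge of the tree"
            )
        seen_sites = set()
        for ch in rec.raw_changes:
            if not 1 <= ch.site <= alignment_length:
                raise MalformedBlockError(
                    f"site {ch.site} outside alignment of length "
                    f"{alignment_length} on branch "
                    f"{rec.parent}..{rec.child}"
                )
            if ch.site in seen_sites:
                raise MalformedBlockError(
                    f"site {ch.site} listed twice on branch "
                    f"{rec.parent}..{rec.child}"
                )
            seen_sites.add(ch.site)

    taxa = sorted(tree.tip_names.items())
    return RstDocument(
        program_tag=program,
        alignment_length=alignment_length,
        taxa=taxa,
        tree=tree,
        branches=branches,
        node_sequences=node_sequences,
    )


def _parse_change_line(line: str, program: str, lineno: int) -> RawChange:
    if program == CODEML:
        m = _CODEML_CHANGE.match(line)
        if not m:
            raise MalformedBlockError(
                f"unparseable codeml change line: {line!r}", lineno
            )
        site, from_codon, from_aa, prob, to_codon, to_aa = m.groups()
        _check_states(from_codon, to_codon, lineno)
        return RawChange(
            site=int(site),
            from_state=from_codon,
            to_state=to_codon,
            from_aa=from_aa,
            to_aa=to_aa,
            posterior=float(prob),
        )
    m = _BASEML_CHANGE.match(line)
    if not m:
        raise MalformedBlockError(
            f"unparseable baseml change line: {line!r}", lineno
        )
    site, from_base, prob, to_base = m.groups()
    _check_states(from_base, to_base, lineno)
    return RawChange(
        site=int(site),
        from_state=from_base,
        to_state=to_base,
        posterior=float(prob),
    )


def _check_states(from_state: str, to_state: str, lineno: int) -> None:
    if set(from_state) - _DNA or set(to_state) - _DNA:
        raise GapOrAmbiguityError(
            f"line {lineno}: non-ACGT state in change "
            f"{from_state} -> {to_state}"
        )
    if from_state == to_state:
        raise MalformedBlockError(
            f"change with identical states: {from_state}", lineno
        )


def read_rst(path) -> RstDocument:
    """Read and parse an rst file from disk."""
    with open(path, encoding="utf-8") as fh:
        return parse_rst(fh.read())
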