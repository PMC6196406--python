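"""Codon-sequence evolution simulator with an exact event log.

The simulator exists for format and count fidelity, not biological
realism: it evolves a gap-free coding sequence down a random (or given)
rooted binary tree, records every substitution it places, and serializes
the result in the same reconstruction-file dialect the parser reads. The
:class:`GroundTruthLog` is the oracle against which the parser, classifier
and every downstream tally are checked.

Model: the root sequence is uniform over the 61 sense codons; each branch
receives a Poisson-distributed number of substitutions at distinct sites;
the derived base is drawn with transition:transversion odds kappa : 1,
split evenly between the two possible transversions (relative weights
kappa, 0.5, 0.5). Proposals that would create a stop codon — judged both
against the parent codon with the single site altered and against the
accumulating child sequence — are rejected and redrawn, so no node
sequence ever contains an in-frame stop. This is not a GY94-style codon
model: there is no omega, no rate heterogeneity, no branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import codon_index, codon_position, substitution_class
from .errors import ParameterError
from .genetic_code import DNA_BASES, SENSE_CODONS, is_stop, is_synonymous
from .trees import Branch, TreeTopology

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SimEvent:
    """One simulated substitution, pre-classified by construction."""

    branch: Branch
    site: int
    from_base: str
    to_base: str
    from_codon: str  # parent-context codon (single site altered in to_codon)
    to_codon: str
    mutation_class: str
    effect: str
    category: str
    posterior: float


@dataclass
class GroundTruthLog:
    """Exact record of a simulated history."""

    tree: TreeTopology
    node_sequences: dict[int, str]
    events: list[SimEvent]
    seed: int
    kappa: float
    events_per_branch: float
    length_codons: int

    @property
    def length_nt(self) -> int:
        return 3 * self.length_codons

    def category_totals(self) -> dict[str, int]:
        totals = {"As": 0, "Bs": 0, "Aa": 0, "Ba": 0}
        for ev in self.events:
            totals[ev.category] += 1
        return totals

    def branch_totals(self) -> dict[Branch, int]:
        totals: dict[Branch, int] = {}
        for ev in self.events:
            totals[ev.branch] = totals.get(ev.branch, 0) + 1
        return totals

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent": ev.branch[0], "child": ev.branch[1],
                "site": ev.site, "from_base": ev.from_base,
                "to_base": ev.to_base, "from_codon": ev.from_codon,
                "to_codon": ev.to_codon, "class": ev.mutation_class,
                "effect": ev.effect, "category": ev.category,
                "posterior": ev.posterior,
            }
            for ev in self.events
        ]
        return pd.DataFrame(rows)


def random_topology(n_tips: int, rng: np.random.Generator) -> TreeTopology:
    """Random rooted binary topology with PAML-style node numbering.

    Tips are 1..n; internal nodes are renumbered in preorder from the root
    so they occupy n+1..2n-1 with the root at n+1, matching how PAML
    numbers reconstruction nodes.
    """
    if n_tips < 2:
        raise ParameterError("need at least 2 tips")
    # random sequential joins, then renumber internals in preorder
    subtrees = list(range(1, n_tips + 1))
    children: dict[int, tuple[int, int]] = {}
    next_id = n_tips + 1
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        children[next_id] = (a, b)
        subtrees.append(next_id)
        next_id += 1
    old_root = subtrees[0]

    renumber: dict[int, int] = {}
    counter = n_tips + 1
    stack = [old_root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        if node in children:
            stack.extend(reversed(children[node]))
    for node in order:
        if node in children:
            renumber[node] = counter
            counter += 1
        else:
            renumber[node] = node

    parent: dict[int, int] = {}
    for par, kids in children.items():
        for child in kids:
            parent[renumber[child]] = renumber[par]
    tip_names = {i: f"taxon{i}" for i in range(1, n_tips + 1)}
    return TreeTopology(parent=parent, tip_names=tip_names,
                        root=renumber[old_root])


def _draw_target(base: str, rng: np.random.Generator, kappa: float) -> str:
    ts = _TS_PARTNER[base]
    tvs = [b for b in DNA_BASES if b != base and b != ts]
    weights = np.array([kappa, 0.5, 0.5])
    choice = rng.choice(3, p=weights / weights.sum())
    return ([ts] + tvs)[choice]


def simulate(
    tree: TreeTopology | None = None,
    n_tips: int = 10,
    length_codons: int = 300,
    kappa: float = 2.0,
    events_per_branch: float = 20.0,
    seed: int = 0,
) -> GroundTruthLog:
    """Simulate a substitution history and return its exact log.

    Either pass a ``tree`` or let a random topology with ``n_tips`` tips be
    drawn. Fully reproducible from ``seed``.
    """
    if length_codons < 1:
        raise ParameterError("length_codons must be >= 1")
    if kappa <= 0:
        raise ParameterError("kappa must be > 0")
    if events_per_branch < 0:
        raise ParameterError("events_per_branch must be >= 0")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = random_topology(n_tips, rng)

    length_nt = 3 * length_codons
    root_seq = "".join(
        rng.choice(SENSE_CODONS) for _ in range(length_codons)
    )
    node_sequences = {tree.root: root_seq}
    events: list[SimEvent] = []

    for branch in tree.branches:  # preorder: parents are always done first
        parent_seq = node_sequences[branch[0]]
        child = list(parent_seq)
        n_events = int(rng.poisson(events_per_branch))
        n_events = min(n_events, length_nt)  # sites must stay distinct
        used_sites: set[int] = set()
        placed = 0
        attempts = 0
        max_attempts = 1000 * (n_events + 1)
        while placed < n_events:
            attempts += 1
            if attempts > max_attempts:  # pathological site saturation
                raise ParameterError(
                    "could not place requested substitutions without "
                    "creating stop codons; lower events_per_branch or "
                    "increase length_codons"
                )
            site = int(rng.integers(1, length_nt + 1))
            if site in used_sites:
                continue
            pos = codon_position(site)
            ci = codon_index(site)
            from_base = child[site - 1]
            to_base = _draw_target(from_base, rng, kappa)
            parent_codon = parent_seq[3 * (ci - 1): 3 * ci]
            ctx_codon = (
                parent_codon[: pos - 1] + to_base + parent_codon[pos:]
            )
            child_codon = "".join(child[3 * (ci - 1): 3 * ci])
            child_codon = (
                child_codon[: pos - 1] + to_base + child_codon[pos:]
            )
            # reject if either the parent-context codon or the codon in the
            # accumulating child sequence becomes a stop
            if is_stop(ctx_codon) or is_stop(child_codon):
                continue
            child[site - 1] = to_base
            used_sites.add(site)
            placed += 1
            mclass = substitution_class(from_base, to_base)
            synonymous = is_synonymous(parent_codon, ctx_codon)
            events.append(
                SimEvent(
                    branch=branch,
                    site=site,
                    from_base=parent_codon[pos - 1],
                    to_base=to_base,
                    from_codon=parent_codon,
                    to_codon=ctx_codon,
                    mutation_class=mclass,
                    effect="synonymous" if synonymous else "nonsynonymous",
                    category=(
                        ("As" if mclass == "Ts" else "Bs")
                        if synonymous
                        else ("Aa" if mclass == "Ts" else "Ba")
                    ),
                    posterior=round(float(rng.uniform(0.90, 1.00)), 3),
                )
            )
        node_sequences[branch[1]] = "".join(child)

    events.sort(key=lambda e: (e.branch, e.site))
    return GroundTruthLog(
        tree=tree,
        node_sequences=node_sequences,
        events=events,
        seed=seed,
        kappa=kappa,
        events_per_branch=events_per_branch,
        length_codons=length_codons,
    )


def write_rst(log: GroundTruthLog, dialect: str = "codeml") -> str:
    """Serialize a simulated history in the reconstruction-file dialect.

    Emits the same grammar the parser reads: program header, numbered-node
    tree, node sequence list, and one branch block per tree edge (empty
    blocks for branches without events). ``dialect`` selects baseml-style
    base change lines or codeml-style codon (amino acid) lines; sites are
    1-based nucleotide positions in both.
    """
    from .genetic_code import translate
    from .trees import to_numbered_newick

    if dialect not in ("baseml", "codeml"):
        raise ParameterError(f"unknown dialect: {dialect!r}")
    tree = log.tree
    lines: list[str] = []
    lines.append(
        f"Supplemental results for {dialect.upper()} "
        "(seqf: alignment.phy  treef: tree.nwk)"
    )
    lines.append("")
    lines.append("tree with node labels for Rod Page's TreeView")
    lines.append(to_numbered_newick(tree).strip())
    lines.append("")
    lines.append("List of extant and reconstructed sequences")
    lines.append("")
    lines.append(f"{len(tree.nodes):6d} {log.length_nt:8d}")
    lines.append("")
    for node in sorted(log.node_sequences):
        seq = log.node_sequences[node]
        if dialect == "codeml":
            seq = " ".join(seq[i:i + 3] for i in range(0, len(seq), 3))
        lines.append(f"node #{node}   {seq}")
    lines.append("")
    lines.append("Summary of changes along branches.")
    lines.append("Check root of tree for directions of change.")
    lines.append("")
    by_branch: dict[Branch, list[SimEvent]] = {b: [] for b in tree.branches}
    for ev in log.events:
        by_branch[ev.branch].append(ev)
    for i, branch in enumerate(tree.branches, start=1):
        par, child = branch
        label = f" ({tree.tip_names[child]})" if tree.is_tip(child) else ""
        lines.append(f"Branch {i}: {par:5d}..{child}{label}")
        lines.append("")
        for ev in sorted(by_branch[branch], key=lambda e: e.site):
            if dialect == "codeml":
                lines.append(
                    f"\t{ev.site:6d} {ev.from_codon} "
                    f"({translate(ev.from_codon)}) {ev.posterior:.3f} -> "
                    f"{ev.to_codon} ({translate(ev.to_codon)})"
                )
            else:
                lines.append(
                    f"\t{ev.site:6d} {ev.from_base} {ev.posterior:.3f} "
                    f"-> {ev.to_base}"
                )
        lines.append("")
    return "\n".join(lines) + "\n"
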