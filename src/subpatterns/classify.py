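"""Classification of raw inferred changes into substitution events.

Every change becomes a :class:`SubstitutionEvent` carrying three orthogonal
labels:

* mutation class — transition (Ts: A<->G, C<->T) or transversion (Tv: the
  four purine<->pyrimidine pairs);
* codon position 1/2/3 of the changed nucleotide;
* phenotypic effect — synonymous or nonsynonymous, judged by translating
  the codon before and after the change.

The four-way category is the product of class and effect: As (synonymous
Ts), Bs (synonymous Tv), Aa (nonsynonymous Ts), Ba (nonsynonymous Tv).

Codon context is taken from the PARENT node's reconstructed sequence, with
only the changed site altered. PAML reports changes parent->child, so the
pre-substitution reading frame is the parent's; when several sites of one
codon change on the same branch, each change is judged against the parent
codon with only that one site altered, i.e. co-occurring changes are
treated independently (see the methods note for the rationale and limits).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

from .errors import (
    InvalidBaseError,
    MissingAncestorError,
    SiteOutOfRangeError,
    StopCodonError,
)
from .genetic_code import DNA_BASES, is_synonymous, translate
from .rst_io import RstDocument, CODEML
from .trees import Branch

logger = logging.getLogger(__name__)

TS_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})

#: the four categories, in conventional order.
CATEGORIES = ("As", "Bs", "Aa", "Ba")


def substitution_class(from_base: str, to_base: str) -> str:
    """Return "Ts" for transitions, "Tv" for transversions (symmetric)."""
    if from_base not in DNA_BASES or to_base not in DNA_BASES:
        raise InvalidBaseError(f"not DNA bases: {from_base!r}, {to_base!r}")
    if from_base == to_base:
        raise InvalidBaseError(f"identical bases are not a change: {from_base}")
    return "Ts" if frozenset((from_base, to_base)) in TS_PAIRS else "Tv"


def codon_position(site: int) -> int:
    """Codon position (1, 2 or 3) of a 1-based nucleotide site."""
    if site < 1:
        raise SiteOutOfRangeError(f"site must be >= 1, got {site}")
    return (site - 1) % 3 + 1


def codon_index(site: int) -> int:
    """1-based codon number containing a 1-based nucleotide site."""
    if site < 1:
        raise SiteOutOfRangeError(f"site must be >= 1, got {site}")
    return (site - 1) // 3 + 1


@dataclass(frozen=True)
class SubstitutionEvent:
    """One classified substitution on one branch at one site."""

    branch: Branch
    site: int
    codon_index: int
    codon_position: int
    from_base: str
    to_base: str
    from_codon: str
    to_codon: str
    mutation_class: str  # "Ts" | "Tv"
    effect: str  # "synonymous" | "nonsynonymous"
    category: str  # "As" | "Bs" | "Aa" | "Ba"
    posterior: float | None = None

    @property
    def from_aa(self) -> str:
        return translate(self.from_codon)

    @property
    def to_aa(self) -> str:
        return translate(self.to_codon)


def _category(mutation_class: str, synonymous: bool) -> str:
    if mutation_class == "Ts":
        return "As" if synonymous else "Aa"
    return "Bs" if synonymous else "Ba"


def build_events(
    doc: RstDocument, min_posterior: float = 0.0
) -> list[SubstitutionEvent]:
    """Classify every raw change in a parsed rst document.

    Changes with a posterior below ``min_posterior`` are dropped (default
    0.0: all inferred changes are counted). Raises
    :class:`MissingAncestorError` if a branch's parent sequence is absent
    and :class:`StopCodonError` if any implied codon is a stop.
    """
    events: list[SubstitutionEvent] = []
    for rec in doc.branches:
        parent_seq = doc.node_sequences.get(rec.parent)
        if parent_seq is None:
            raise MissingAncestorError(
                f"no reconstructed sequence for ancestral node {rec.parent}"
            )
        for ch in rec.raw_changes:
            if ch.posterior is not None and ch.posterior < min_posterior:
                continue
            ci = codon_index(ch.site)
            pos = codon_position(ch.site)
            parent_codon = parent_seq[3 * (ci - 1): 3 * ci]
            if len(parent_codon) < 3:
                raise SiteOutOfRangeError(
                    f"site {ch.site} has no complete codon in an alignment "
                    f"of length {doc.alignment_length}"
                )
            if len(ch.to_state) == 3:  # codeml: states are codons
                from_base = ch.from_state[pos - 1]
                to_base = ch.to_state[pos - 1]
            else:
                from_base = ch.from_state
                to_base = ch.to_state
            if parent_codon[pos - 1] != from_base:
                logger.warning(
                    "branch %d..%d site %d: ancestral base %s disagrees "
                    "with change line origin %s",
                    rec.parent, rec.child, ch.site,
                    parent_codon[pos - 1], from_base,
                )
            from_codon = parent_codon
            to_codon = (
                parent_codon[: pos - 1] + to_base + parent_codon[pos:]
            )
            try:
                synonymous = is_synonymous(from_codon, to_codon)
            except StopCodonError as exc:
                raise StopCodonError(
                    f"branch {rec.parent}..{rec.child} site {ch.site}: {exc}"
                ) from exc
            if ch.from_aa and doc.program_tag == CODEML:
                if translate(from_codon) != ch.from_aa or (
                    translate(to_codon) != ch.to_aa
                ):
                    logger.warning(
                        "branch %d..%d site %d: printed amino acids "
                        "%s->%s disagree with translation %s->%s",
                        rec.parent, rec.child, ch.site,
                        ch.from_aa, ch.to_aa,
                        translate(from_codon), translate(to_codon),
                    )
            mclass = substitution_class(from_base, to_base)
            events.append(
                SubstitutionEvent(
                    branch=(rec.parent, rec.child),
                    site=ch.site,
                    codon_index=ci,
                    codon_position=pos,
                    from_base=from_base,
                    to_base=to_base,
                    from_codon=from_codon,
                    to_codon=to_codon,
                    mutation_class=mclass,
                    effect="synonymous" if synonymous else "nonsynonymous",
                    category=_category(mclass, synonymous),
                    posterior=ch.posterior,
                )
            )
    events.sort(key=lambda e: (e.branch, e.site))
    return events
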