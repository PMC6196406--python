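"""Standard genetic code: translation and synonymy tests.

The synonymous/nonsynonymous split of substitutions needs nothing more than
codon translation under the standard (id 1) code, which is taken from
Biopython's table rather than re-typed here. Alternative code tables are out
of scope, but everything downstream goes through :data:`CODON_TABLE`, which
is a plain mapping and therefore swappable.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .errors import InvalidCodonError, StopCodonError

STOP = "*"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with "*" for the three stops.
CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
CODON_TABLE.update({c: STOP for c in _standard.stop_codons})

#: the 61 sense codons of the standard code, in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != STOP)
)

DNA_BASES = "ACGT"


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(b not in DNA_BASES for b in codon):
        raise InvalidCodonError(f"not a valid DNA codon: {codon!r}")
    return codon


def translate(codon: str) -> str:
    """Translate a codon to its one-letter amino acid ('*' for stops)."""
    return CODON_TABLE[_check_codon(codon)]


def is_stop(codon: str) -> bool:
    return CODON_TABLE[_check_codon(codon)] == STOP


def is_synonymous(from_codon: str, to_codon: str) -> bool:
    """True iff two differing sense codons encode the same amino acid.

    Stop codons are rejected: in a valid coding alignment no inferred state
    is a stop, so encountering one signals corrupt input rather than a
    legitimate synonymy question.
    """
    aa_from = translate(from_codon)
    aa_to = translate(to_codon)
    if STOP in (aa_from, aa_to):
        raise StopCodonError(
            f"stop codon in synonymy test: {from_codon} -> {to_codon}"
        )
    return aa_from == aa_to
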