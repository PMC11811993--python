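"""In-silico proteolytic digestion and theoretical peptide counting.

iBAQ normalisation divides a protein's summed (here: median-aggregated) LFQ
intensity by the number of theoretical tryptic peptides its sequence can
produce, so the digestion rules directly determine the absolute scale of every
iBAQ value.  The default rules model trypsin: cleavage C-terminal of lysine
(K) or arginine (R), suppressed when the next residue is proline (P), no
missed cleavages, and only peptides of 7-30 residues counted (the range a
typical DIA search considers identifiable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DigestionRules:
    """Cleavage specificity and peptide length window for in-silico digestion.

    Attributes
    ----------
    cleave_after : frozenset of residues after which the backbone is cut.
    suppress_before : residues that block a cut when they follow the site.
    min_length, max_length : inclusive peptide length window.
    missed_cleavages : maximum number of internal uncut sites per peptide.
    """

    cleave_after: frozenset = frozenset("KR")
    suppress_before: frozenset = frozenset("P")
    min_length: int = 7
    max_length: int = 30
    missed_cleavages: int = 0

    def __post_init__(self):
        if not (1 <= self.min_length <= self.max_length):
            raise InvalidParameterError(
                f"require 1 <= min_length <= max_length, got "
                f"{self.min_length}..{self.max_length}"
            )
        if self.missed_cleavages < 0:
            raise InvalidParameterError("missed_cleavages must be >= 0")


def cleavage_fragments(sequence: str, rules: DigestionRules) -> list[str]:
    """Split ``sequence`` at every allowed cleavage site (fully cleaved fragments)."""
    bounds = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in rules.cleave_after and sequence[i + 1] not in rules.suppress_before:
            bounds.append(i + 1)
    bounds.append(len(sequence))
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]


def digest_tryptic(sequence: str, rules: DigestionRules = DigestionRules()) -> list[str]:
    """Digest a protein sequence, returning the distinct in-range peptides.

    With ``missed_cleavages = m`` every concatenation of up to ``m + 1``
    adjacent fully-cleaved fragments is emitted.  Peptides outside the
    length window are discarded; duplicates (repeated tracts) are counted
    once.  The result is sorted for determinism.  An empty sequence yields
    an empty list.
    """
    frags = cleavage_fragments(sequence, rules)
    peptides: set[str] = set()
    for i in range(len(frags)):
        piece = ""
        for j in range(i, min(i + rules.missed_cleavages + 1, len(frags))):
            piece += frags[j]
            if len(piece) > rules.max_length:
                break
            if len(piece) >= rules.min_length:
                peptides.add(piece)
    return sorted(peptides)


@dataclass
class PeptideCounts:
    """Theoretical peptide counts per gene, with zero-count genes flagged."""

    counts: pd.Series
    zero_count_genes: frozenset = field(default_factory=frozenset)


def count_theoretical_peptides(db, rules: DigestionRules = DigestionRules()) -> PeptideCounts:
    """Count distinct in-range tryptic peptides for every gene in ``db``.

    Genes whose canonical sequence yields no peptide inside the length window
    cannot receive an iBAQ value (division by zero); they are returned with
    count 0 and collected in ``zero_count_genes``.
    """
    if len(db) == 0:
        raise InvalidParameterError("empty sequence database")
    per_gene: dict[str, set[str]] = {}
    for entry in db:
        per_gene.setdefault(entry.gene, set()).update(digest_tryptic(entry.sequence, rules))
    counts = pd.Series({g: len(p) for g, p in sorted(per_gene.items())}, dtype=int)
    counts.index.name = "gene"
    zeros = frozenset(counts.index[counts == 0])
    if zeros:
        logger.warning("%d genes yield no theoretical peptide in range", len(zeros))
    return PeptideCounts(counts=counts, zero_count_genes=zeros)
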