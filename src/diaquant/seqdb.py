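"""Protein sequence database container ("one protein sequence per gene").

Protein abundances downstream are reported per gene identifier (the UniProt
"canonical protein" convention), so the database maps each accession to a
single gene and sequence, carries an organism tag used to tell target from
entrapment entries, and flags contaminant (cRAP-style) accessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .digestion import AMINO_ACIDS
from .errors import IntegrityError

_VALID_RESIDUES = set(AMINO_ACIDS) | {"U", "X", "B", "Z", "J", "O"}  # tolerate ambiguity codes


@dataclass(frozen=True)
class DBEntry:
    accession: str
    gene: str
    sequence: str
    organism: str
    is_contaminant: bool = False


class ProteinSequenceDB:
    """Accession-keyed map of canonical protein sequences.

    Duplicate accessions and empty sequences are rejected at insertion so a
    loaded database always satisfies its uniqueness invariants.
    """

    def __init__(self, entries: Iterable[DBEntry] = ()):
        self._entries: dict[str, DBEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: DBEntry) -> None:
        if entry.accession in self._entries:
            raise IntegrityError(f"duplicate accession {entry.accession!r}")
        if not entry.sequence:
            raise IntegrityError(f"empty sequence for accession {entry.accession!r}")
        bad = set(entry.sequence) - _VALID_RESIDUES
        if bad:
            raise IntegrityError(
                f"non-amino-acid characters {sorted(bad)} in {entry.accession!r}"
            )
        self._entries[entry.accession] = entry

    def merge(self, other: "ProteinSequenceDB") -> "ProteinSequenceDB":
        """Union of two databases (duplicate accessions rejected)."""
        return ProteinSequenceDB(list(self) + list(other))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[DBEntry]:
        return iter(self._entries.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def __getitem__(self, accession: str) -> DBEntry:
        return self._entries[accession]

    @property
    def accessions(self) -> list[str]:
        return list(self._entries)

    @property
    def genes(self) -> set[str]:
        return {e.gene for e in self}

    def genes_with_tag(self, organism: str) -> set[str]:
        return {e.gene for e in self if e.organism == organism}

    @property
    def contaminant_accessions(self) -> set[str]:
        return {e.accession for e in self if e.is_contaminant}

    def to_fasta(self, path: str | Path) -> None:
        """Write ``>accession GN=gene OS=organism`` FASTA records."""
        with open(path, "w") as fh:
            for e in self:
                fh.write(f">{e.accession} GN={e.gene} OS={e.organism}\n")
                for i in range(0, len(e.sequence), 60):
                    fh.write(e.sequence[i : i + 60] + "\n")
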