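"""Organism-tagged protein sequence databases.

FASTA headers follow ``>record_id organism=<tag> family=<id>``; the family
tag is optional and only present for synthetic databases where the truth is
known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Record:
    id: str
    organism: str
    seq: str
    family: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinDatabase:
    """A collection of protein records with stable identifiers."""

    records: list[Record] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[str, Record] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(f"duplicate record identifier: {rec.id}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> Record:
        return self._index[record_id]

    def add(self, rec: Record) -> None:
        if rec.id in self._index:
            raise ValueError(f"duplicate record identifier: {rec.id}")
        self.records.append(rec)
        self._index[rec.id] = rec

    @property
    def organisms(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.organism, None)
        return list(seen)

    @property
    def total_residues(self) -> int:
        return sum(len(r.seq) for r in self.records)

    def by_organism(self, organism: str) -> list[Record]:
        return [r for r in self.records if r.organism == organism]

    @classmethod
    def from_fasta(cls, paths: str | Path | Iterable[str | Path]) -> "ProteinDatabase":
        """Load one or more FASTA files.

        Organism is read from the ``organism=`` header tag; if a file has no
        tags, the file stem is used as the organism for all its records.
        """
        if isinstance(paths, (str, Path)):
            paths = [paths]
        records = []
        for path in paths:
            path = Path(path)
            for sr in SeqIO.parse(str(path), "fasta"):
                tags = dict(
                    part.split("=", 1)
                    for part in sr.description.split()[1:]
                    if "=" in part
                )
                organism = tags.get("organism", path.stem)
                records.append(
                    Record(
                        id=sr.id,
                        organism=organism,
                        seq=str(sr.seq),
                        family=tags.get("family"),
                    )
                )
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        seq_records = []
        for rec in self.records:
            desc = f"organism={rec.organism}"
            if rec.family is not None:
                desc += f" family={rec.family}"
            seq_records.append(SeqRecord(Seq(rec.seq), id=rec.id, description=desc))
        SeqIO.write(seq_records, str(path), "fasta")
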