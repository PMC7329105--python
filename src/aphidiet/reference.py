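"""Labeled COI barcode reference libraries.

A reference library is the substrate for marker-resolution analysis and for
taxonomic assignment of pipeline centroids.  Records carry a genus label, an
optional species label (genus-only records model taxa that could not be
identified to species) and an optional taxon-group label (e.g. ``aphid`` /
``coccinellid``) used by primer coverage reports.

FASTA convention: ``>id|genus|species|group`` with trailing fields optional;
a sidecar TSV (columns id, genus, species, group) may override headers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._iupac import validate


@dataclass(frozen=True)
class ReferenceRecord:
    """One labeled barcode sequence."""

    id: str
    genus: str
    sequence: str
    species: str | None = None
    group: str = ""
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError(f"record {self.id!r}: genus must be non-empty")
        validate(self.sequence)

    @property
    def taxon(self) -> str:
        """``Genus species`` or ``Genus sp.`` for genus-only records."""
        return f"{self.genus} {self.species}" if self.species else f"{self.genus} sp."


class ReferenceLibrary:
    """An ordered collection of :class:`ReferenceRecord` with unique ids."""

    def __init__(self, records: Iterable[ReferenceRecord] = ()) -> None:
        self.records: list[ReferenceRecord] = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> ReferenceRecord:
        return self.records[idx]

    def genera(self) -> list[str]:
        return sorted({r.genus for r in self.records})

    def by_genus(self, genus: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.genus == genus]

    def by_group(self) -> dict[str, list[ReferenceRecord]]:
        out: dict[str, list[ReferenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.group, []).append(r)
        return out

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(
        cls, path: str | Path, taxonomy_tsv: str | Path | None = None
    ) -> "ReferenceLibrary":
        """Read ``>id|genus|species|group`` FASTA, optionally with sidecar TSV."""
        sidecar: dict[str, dict[str, str]] = {}
        if taxonomy_tsv is not None:
            with open(taxonomy_tsv, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    sidecar[row["id"]] = row
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.description.split("|")
            rid = fields[0].split()[0]
            meta = sidecar.get(rid)
            if meta is not None:
                genus = meta.get("genus", "")
                species = meta.get("species") or None
                group = meta.get("group", "")
            else:
                genus = fields[1] if len(fields) > 1 else ""
                species = fields[2] if len(fields) > 2 and fields[2] else None
                group = fields[3] if len(fields) > 3 else ""
            records.append(
                ReferenceRecord(
                    id=rid, genus=genus, species=species, group=group,
                    sequence=str(rec.seq).upper(),
                )
            )
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(
                Seq(r.sequence),
                id=f"{r.id}|{r.genus}|{r.species or ''}|{r.group}",
                description="",
            )
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")
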