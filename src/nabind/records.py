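"""Protein records and their plain-text IO.

A :class:`ProteinRecord` carries a sequence plus, optionally, per-residue
binary binding labels (residue-level task) and/or a protein-level binary
label (binder / non-binder classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    residue_labels: Optional[np.ndarray] = None
    protein_label: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.residue_labels is not None:
            self.residue_labels = np.asarray(self.residue_labels, dtype=np.int8)
            if self.residue_labels.shape != (len(self.sequence),):
                raise ValueError(
                    f"record {self.id!r}: label length {self.residue_labels.shape} "
                    f"!= sequence length {len(self.sequence)}"
                )
            if not np.isin(self.residue_labels, (0, 1)).all():
                raise ValueError(f"record {self.id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def label_string(self) -> str:
        if self.residue_labels is None:
            return ""
        return "".join(str(int(x)) for x in self.residue_labels)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(id=r.id, sequence=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_label_tsv(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """One row per protein: id, sequence, 0/1 label string, protein label."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tresidue_labels\tprotein_label\n")
        for r in records:
            plabel = "" if r.protein_label is None else str(int(r.protein_label))
            fh.write(f"{r.id}\t{r.sequence}\t{r.label_string}\t{plabel}\n")


def read_label_tsv(path: str | Path) -> list[ProteinRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            labels = parts[idx["residue_labels"]] if "residue_labels" in idx else ""
            plabel = parts[idx["protein_label"]] if "protein_label" in idx else ""
            records.append(
                ProteinRecord(
                    id=parts[idx["id"]],
                    sequence=parts[idx["sequence"]],
                    residue_labels=(
                        np.array([int(c) for c in labels], dtype=np.int8) if labels else None
                    ),
                    protein_label=int(plabel) if plabel != "" else None,
                )
            )
    return records
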