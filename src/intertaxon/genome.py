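"""Genome container: named, ordered chromosomes of nucleotide sequence.

The genome is the unit of ANI, structural-variant and simulation work.
Sequences are stored as plain uppercase strings (A/C/G/T); coordinates are
0-based half-open internally and converted to 1-based inclusive only at
VCF/GFF/report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered mapping of chromosome name -> nucleotide sequence."""

    chromosomes: dict[str, str] = field(default_factory=dict)
    name: str = "genome"

    def __post_init__(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {chrom!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def gc_content(self) -> float:
        gc = sum(s.count("G") + s.count("C") for s in self.chromosomes.values())
        return gc / self.total_length

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def copy(self, name: str | None = None) -> "Genome":
        return Genome(dict(self.chromosomes), name or self.name)

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "Genome":
        path = Path(path)
        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not chroms:
            raise ValueError(f"no sequences found in {path}")
        return cls(chroms, name or path.stem)

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.chromosomes.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)
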