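"""Gene models for full-length circRNA annotation.

A :class:`GeneModel` holds the ordered exons of a single gene in transcript
orientation, optionally together with the full genomic (exons + introns)
sequence.  Coordinates are 0-based half-open on the transcript-oriented gene
sequence; exon indices are 1-based to match the usual "Exon 1 ... Exon 10"
naming of annotated loci.  Minus-strand input is reverse-complemented once at
load time so that every downstream algorithm is strand-free.

Sequences are stored as uppercase DNA; RNA input (``U``) is converted to
``T`` on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Exon",
    "GeneModel",
    "GeneModelError",
    "load_gene_model",
    "exon_flanks",
    "clean_sequence",
    "reverse_complement",
]

_VALID_BASES = frozenset("ACGT")

#: Sentinel for an intronic flank that cannot be determined.
UNKNOWN_FLANK = "unknown"


class GeneModelError(ValueError):
    """Raised when a gene model violates its invariants."""


def clean_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises :class:`GeneModelError` naming the first offending position if any
    character outside ``{A, C, G, T, U}`` is present.
    """
    out = seq.upper().replace("U", "T")
    for pos, base in enumerate(out):
        if base not in _VALID_BASES:
            raise GeneModelError(
                f"non-ACGT character {base!r} at position {pos} in {context}"
            )
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Exon:
    """One exon of a gene, in transcript orientation.

    ``donor_flank`` is the 2-nt intronic sequence immediately 3' of the exon
    (the start of the downstream intron, canonically ``GT``);
    ``acceptor_flank`` the 2 nt immediately 5' of the exon (the end of the
    upstream intron, canonically ``AG``).  Either is ``"unknown"`` when the
    intron is unavailable or the exon is terminal.
    """

    index: int
    sequence: str
    genomic_start: int
    genomic_end: int
    donor_flank: str = UNKNOWN_FLANK
    acceptor_flank: str = UNKNOWN_FLANK

    def __post_init__(self) -> None:
        if self.index < 1:
            raise GeneModelError(f"exon index must be >= 1, got {self.index}")
        if not self.sequence:
            raise GeneModelError(f"exon {self.index} has an empty sequence")
        if len(self.sequence) != self.genomic_end - self.genomic_start:
            raise GeneModelError(
                f"exon {self.index}: sequence length {len(self.sequence)} != "
                f"interval length {self.genomic_end - self.genomic_start}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """Ordered exons of one gene plus, optionally, the full gene sequence."""

    gene_id: str
    exons: list[Exon] = field(default_factory=list)
    gene_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.exons:
            raise GeneModelError("gene model has no exons")
        indices = [e.index for e in self.exons]
        if indices != list(range(1, len(self.exons) + 1)):
            raise GeneModelError(
                f"exon indices must be 1..n consecutive, got {indices}"
            )
        prev_end = None
        for exon in self.exons:
            if prev_end is not None and exon.genomic_start < prev_end:
                raise GeneModelError(
                    f"overlapping exons at exon {exon.index} "
                    f"(starts {exon.genomic_start} < previous end {prev_end})"
                )
            prev_end = exon.genomic_end
        if self.gene_sequence is not None:
            n = len(self.gene_sequence)
            for exon in self.exons:
                if exon.genomic_end > n:
                    raise GeneModelError(
                        f"exon {exon.index} extends past gene end ({exon.genomic_end} > {n})"
                    )
                if self.gene_sequence[exon.genomic_start : exon.genomic_end] != exon.sequence:
                    raise GeneModelError(
                        f"exon {exon.index} sequence disagrees with gene_sequence slice"
                    )

    # -- accessors --------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> Exon:
        if not 1 <= index <= len(self.exons):
            raise GeneModelError(f"exon index {index} out of range 1..{len(self.exons)}")
        return self.exons[index - 1]

    def genomic_base(self, pos: int) -> Optional[str]:
        """Base at a gene coordinate, or None when outside the known sequence."""
        if self.gene_sequence is not None and 0 <= pos < len(self.gene_sequence):
            return self.gene_sequence[pos]
        return None

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "gene_id": self.gene_id,
            "gene_sequence": self.gene_sequence,
            "exons": [
                {
                    "index": e.index,
                    "sequence": e.sequence,
                    "genomic_start": e.genomic_start,
                    "genomic_end": e.genomic_end,
                    "donor_flank": e.donor_flank,
                    "acceptor_flank": e.acceptor_flank,
                }
                for e in self.exons
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        doc = json.loads(text)
        exons = [Exon(**e) for e in doc["exons"]]
        return cls(gene_id=doc["gene_id"], exons=exons, gene_sequence=doc["gene_sequence"])

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "GeneModel":
        return cls.from_json(Path(path).read_text())

    def write_bed_fasta(self, bed_path: str | Path, fasta_path: str | Path) -> None:
        """Write the exon intervals as BED and the gene sequence as FASTA."""
        if self.gene_sequence is None:
            raise GeneModelError("cannot write BED+FASTA without a gene_sequence")
        lines = [
            f"{self.gene_id}\t{e.genomic_start}\t{e.genomic_end}\texon_{e.index}"
            for e in self.exons
        ]
        Path(bed_path).write_text("\n".join(lines) + "\n")
        Path(fasta_path).write_text(f">{self.gene_id}\n{self.gene_sequence}\n")


def _flanks_from_gene(seq: str, exons: list[Exon]) -> list[Exon]:
    """Populate intronic flanks from the full gene sequence."""
    out = []
    n = len(seq)
    for i, exon in enumerate(exons):
        donor = UNKNOWN_FLANK
        acceptor = UNKNOWN_FLANK
        # donor flank: 2 nt after the exon, only if there is a downstream intron
        if i < len(exons) - 1 and exon.genomic_end + 2 <= exons[i + 1].genomic_start:
            donor = seq[exon.genomic_end : exon.genomic_end + 2]
        # acceptor flank: 2 nt before the exon, only if there is an upstream intron
        if i > 0 and exon.genomic_start - 2 >= exons[i - 1].genomic_end:
            acceptor = seq[exon.genomic_start - 2 : exon.genomic_start]
        out.append(replace(exon, donor_flank=donor, acceptor_flank=acceptor))
    return out


def load_gene_model(
    bed_path: str | Path,
    fasta_path: str | Path,
    gene_id: Optional[str] = None,
    strand: str = "+",
) -> GeneModel:
    """Load a gene model from a BED-like exon table and a FASTA sequence file.

    The BED file (>= 3 columns, 0-based half-open) lists the exon intervals on
    a single contig present in the FASTA.  Minus-strand input
    (``strand="-"``) is reverse-complemented once here; the returned model is
    transcript-oriented.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["contig", "start", "end"],
        dtype={"contig": str, "start": int, "end": int},
    )
    if bed.empty:
        raise GeneModelError(f"no intervals in {bed_path}")
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    names = bed["contig"].unique()
    if len(names) != 1:
        raise GeneModelError(f"expected one contig in the BED file, got {list(names)}")
    contig = names[0]
    if contig not in contigs:
        raise GeneModelError(f"contig {contig!r} absent from {fasta_path}")
    seq = clean_sequence(contigs[contig], context=f"contig {contig}")
    n = len(seq)
    intervals = sorted(zip(bed["start"], bed["end"]))
    for start, end in intervals:
        if start < 0 or end > n:
            raise GeneModelError(f"exon [{start},{end}) outside contig bounds [0,{n})")
        if end <= start:
            raise GeneModelError(f"empty or inverted exon interval [{start},{end})")
    if strand == "-":
        seq = reverse_complement(seq)
        intervals = sorted((n - end, n - start) for start, end in intervals)
    elif strand != "+":
        raise GeneModelError(f"strand must be '+' or '-', got {strand!r}")
    exons = [
        Exon(index=i + 1, sequence=seq[s:e], genomic_start=s, genomic_end=e)
        for i, (s, e) in enumerate(intervals)
    ]
    exons = _flanks_from_gene(seq, exons)
    return GeneModel(gene_id=gene_id or contig, exons=exons, gene_sequence=seq)


def model_from_exon_sequences(gene_id: str, sequences: Iterable[str]) -> GeneModel:
    """Build an intron-less model from exon sequences alone (flanks unknown)."""
    exons = []
    pos = 0
    for i, raw in enumerate(sequences, start=1):
        seq = clean_sequence(raw, context=f"exon {i}")
        exons.append(Exon(index=i, sequence=seq, genomic_start=pos, genomic_end=pos + len(seq)))
        pos += len(seq)
    return GeneModel(gene_id=gene_id, exons=exons, gene_sequence=None)


def exon_flanks(model: GeneModel, index: int) -> tuple[str, str]:
    """Intronic dinucleotides around one exon: ``(donor_flank, acceptor_flank)``.

    The donor flank is the 2 nt immediately 3' of the exon in the gene, the
    acceptor flank the 2 nt immediately 5' of it.  ``"unknown"`` is returned
    for terminal exons (no flanking intron on that side) and when introns are
    unavailable.
    """
    exon = model.exon(index)
    donor, acceptor = exon.donor_flank, exon.acceptor_flank
    if index == 1:
        acceptor = UNKNOWN_FLANK
    if index == model.n_exons:
        donor = UNKNOWN_FLANK
    return donor, acceptor
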