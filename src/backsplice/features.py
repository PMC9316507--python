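"""Functional characterization of confirmed circRNAs.

Scanners here respect circularity: a feature may span the back-splice
junction, in which case any single linear cut of the sequence hides it.
ORF finding therefore supports three modes — the two linearizations
(cut at the BSJ, cut at the adjacent splice site) that a linear-only ORF
tool forces, and a genuinely circular scan across the junction — plus
TargetScan-style miRNA seed-site classes (8mer, 7mer-m8, 7mer-A1), the
DRACH m6A consensus, and generic IUPAC motif counting for RNA-binding
proteins with an optional dinucleotide-shuffle empirical p-value.

Positions are 0-based circular coordinates on the canonical rotation
(position 0 = the acceptor's first retained base, i.e. immediately 3' of
the BSJ).  Motif and context strings are rendered as RNA, as they read on
the target.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .gene_model import clean_sequence
from .circrna import CircRNA

__all__ = [
    "ORFRecord",
    "SeedSite",
    "M6ASite",
    "RBPCount",
    "find_orfs",
    "translate",
    "scan_protein_motifs",
    "scan_mirna_sites",
    "scan_m6a",
    "scan_rbp_motifs",
    "dinucleotide_shuffle",
    "MOTIF_I",
    "MOTIF_POST_I",
]

#: Methyltransferase signature motifs carried by arginine methyltransferases.
MOTIF_I = "VLDVGSGTG"
MOTIF_POST_I = "VIGIE"

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOP_CODONS = set(_STANDARD.stop_codons)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_DRACH = ("AGT", "AG", "A", "C", "ACT")


def _to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def _seq_of(circ: Union[CircRNA, str]) -> str:
    seq = circ.sequence if isinstance(circ, CircRNA) else circ
    return clean_sequence(seq, context="circRNA sequence")


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORFRecord:
    mode: str                  # linearized_bsj | linearized_adjacent | circular
    start_position: int        # circular coordinate of the A of ATG
    length_aa: int
    peptide: str
    crosses_bsj: bool
    stop_found: bool


def translate(orf_nucleotides: str) -> str:
    """Standard-code translation of a claimed ORF.

    The trailing stop codon, if present, is removed before translation; an
    internal stop violates the ORF contract and raises ``ValueError``.
    """
    seq = clean_sequence(orf_nucleotides, context="ORF")
    if len(seq) % 3:
        raise ValueError(f"ORF length {len(seq)} is not a multiple of 3")
    if seq[-3:] in _STOP_CODONS:
        seq = seq[:-3]
    peptide = str(Seq(seq).translate())
    if "*" in peptide:
        raise ValueError("internal stop codon in claimed ORF")
    return peptide


def _linear_orfs(linear: str, cut: int, L: int, mode: str, min_aa: int) -> list[ORFRecord]:
    """ORF-Finder-style scan of one linearization: per frame, the 5'-most ATG
    of each stop-to-stop segment; ORFs reaching the cut end are reported with
    ``stop_found=False``."""
    out = []
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, len(linear) - 2, 3):
            codon = linear[pos : pos + 3]
            if codon in _STOP_CODONS:
                if start is not None:
                    n_aa = (pos - start) // 3
                    if n_aa >= min_aa:
                        out.append(_linear_record(linear, start, pos, cut, L, mode, True))
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        if start is not None:
            end = start + 3 * ((len(linear) - start) // 3)
            n_aa = (end - start) // 3
            if n_aa >= min_aa:
                out.append(_linear_record(linear, start, end, cut, L, mode, False))
    return out


def _linear_record(linear, start, end, cut, L, mode, stop_found) -> ORFRecord:
    peptide = str(Seq(linear[start:end]).translate())
    circ_start = (cut + start) % L
    circ_end_excl = cut + end + (3 if stop_found else 0)
    return ORFRecord(
        mode=mode,
        start_position=circ_start,
        length_aa=len(peptide),
        peptide=peptide,
        crosses_bsj=circ_start + (circ_end_excl - (cut + start)) > L,
        stop_found=stop_found,
    )


def find_orfs(
    circ: Union[CircRNA, str],
    mode: str = "circular",
    min_aa: int = 51,
) -> list[ORFRecord]:
    """Open reading frames of a circRNA under one of three scan modes.

    ``linearized_bsj`` cuts the circle at the back-splice junction and
    ``linearized_adjacent`` at the next splice boundary (the end of the
    acceptor's retained segment); both then scan the three forward frames of
    the resulting linear string, reporting per frame the 5'-most ATG of each
    stop-delimited segment.  ``circular`` scans every ATG on the circle and
    translates across the junction; an ORF that never meets an in-frame stop
    within one extra full period is reported with ``stop_found=False`` and
    capped at ``len(circ) // 3`` codons.

    ``min_aa`` retains ORFs of at least that many amino acids (default 51,
    i.e. peptides of more than 50 residues; the stop codon never counts).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = _seq_of(circ)
    L = len(seq)
    if L < 3:
        raise ValueError("circRNA shorter than one codon")
    if mode == "linearized_bsj":
        return _linear_orfs(seq, 0, L, mode, min_aa)
    if mode == "linearized_adjacent":
        cut = circ.segments[0][1][1] - circ.segments[0][1][0] if isinstance(circ, CircRNA) else 0
        cut %= L
        rotated = seq[cut:] + seq[:cut]
        return _linear_orfs(rotated, cut, L, mode, min_aa)
    if mode != "circular":
        raise ValueError(f"unknown ORF mode {mode!r}")

    extended = seq * 3  # enough to read one full extra period from any start
    cap = L // 3
    out = []
    for start in range(L):
        if extended[start : start + 3] != "ATG":
            continue
        peptide_len = 0
        stop_found = False
        pos = start
        while peptide_len < cap:
            codon = extended[pos : pos + 3]
            if codon in _STOP_CODONS:
                stop_found = True
                break
            peptide_len += 1
            pos += 3
        if peptide_len < min_aa:
            continue
        nts = extended[start : start + 3 * peptide_len]
        out.append(
            ORFRecord(
                mode="circular",
                start_position=start,
                length_aa=peptide_len,
                peptide=str(Seq(nts).translate()),
                crosses_bsj=start + 3 * peptide_len + (3 if stop_found else 0) > L,
                stop_found=stop_found,
            )
        )
    return out


# ---------------------------------------------------------------------------
# peptide motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    pattern: str
    position: int


def scan_protein_motifs(
    peptide: str, motif_set: Optional[Mapping[str, str]] = None
) -> list[MotifHit]:
    """All occurrences of exact amino-acid motifs in a peptide.

    Defaults to the methyltransferase motif I and post-I signatures.
    """
    if motif_set is None:
        motif_set = {"motif_I": MOTIF_I, "post_I": MOTIF_POST_I}
    hits = []
    for name, motif in motif_set.items():
        if not motif:
            raise ValueError(f"empty motif {name!r}")
        start = 0
        while True:
            pos = peptide.find(motif, start)
            if pos < 0:
                break
            hits.append(MotifHit(name, motif, pos))
            start = pos + 1
    return hits


# ---------------------------------------------------------------------------
# miRNA seed sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    site_type: str     # 8mer | 7mer_m8 | 7mer_A1
    motif: str         # RNA string as read on the target, 5'->3'
    position: int      # circular coordinate of the site 5' end
    crosses_bsj: bool


def _load_mirnas(mirnas) -> dict[str, str]:
    if isinstance(mirnas, (str, Path)):
        records = list(SeqIO.parse(str(mirnas), "fasta"))
        pairs = [(r.id, str(r.seq)) for r in records]
    elif isinstance(mirnas, Mapping):
        pairs = list(mirnas.items())
    else:
        pairs = list(mirnas)
    seen: dict[str, str] = {}
    for mid, seq in pairs:
        if mid in seen:
            raise ValueError(f"duplicate miRNA id {mid!r}")
        seq = clean_sequence(seq, context=f"miRNA {mid}")
        if len(seq) < 8:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
        seen[mid] = seq
    return seen


def scan_mirna_sites(circ: Union[CircRNA, str], mirnas) -> list[SeedSite]:
    """Canonical seed-match sites for each miRNA on the circular target.

    Site classes follow the standard seed taxonomy: the target motif for an
    8mer is the reverse complement of miRNA positions 2-8 followed by an A
    (the base opposite miRNA position 1); 7mer-m8 drops the A requirement;
    7mer-A1 pairs only positions 2-7 plus the A.  The scan runs on the
    doubled sequence, so junction-spanning sites are found and flagged.
    """
    from .gene_model import reverse_complement

    seq = _seq_of(circ)
    L = len(seq)
    doubled = seq + seq
    sites = []
    for mid, mseq in _load_mirnas(mirnas).items():
        m28 = reverse_complement(mseq[1:8])      # matches miRNA positions 2-8
        m27 = reverse_complement(mseq[1:7])      # matches positions 2-7
        patterns = [
            ("8mer", m28 + "A"),
            ("7mer_m8", m28),
            ("7mer_A1", m27 + "A"),
        ]
        for pos in range(L):
            for site_type, pat in patterns:
                if doubled[pos : pos + len(pat)] == pat:
                    sites.append(
                        SeedSite(
                            mirna_id=mid,
                            site_type=site_type,
                            motif=_to_rna(pat),
                            position=pos,
                            crosses_bsj=pos + len(pat) > L,
                        )
                    )
                    break  # report the best class per position
    return sites


# ---------------------------------------------------------------------------
# m6A DRACH consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class M6ASite:
    position: int        # circular coordinate of the modified A
    context_9mer: str    # RNA, centered on the A
    consensus: str = "DRACH_match"


def scan_m6a(circ: Union[CircRNA, str]) -> list[M6ASite]:
    """Every adenosine whose centered 5-mer matches the DRACH consensus.

    DRACH: D in {A,G,U}, R in {A,G}, the methylated A, C, H in {A,C,U}.
    The scan is circular; the reported 9-mer context is centered on the A.
    """
    seq = _seq_of(circ)
    L = len(seq)
    ext = seq * 3  # index i+L is circular position i with 4 nt of context both ways
    sites = []
    for i in range(L):
        center = i + L
        if ext[center] != "A":
            continue
        fiver = ext[center - 2 : center + 3]
        if all(fiver[j] in _DRACH[j] for j in range(5)):
            sites.append(
                M6ASite(position=i, context_9mer=_to_rna(ext[center - 4 : center + 5]))
            )
    return sites


# ---------------------------------------------------------------------------
# RBP motif counting
# ---------------------------------------------------------------------------

@dataclass
class RBPCount:
    rbp_name: str
    pattern: str
    count: int
    positions: list[int]
    empirical_p: Optional[float] = None


def _compile_iupac(pattern: str) -> list[str]:
    sets = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern {pattern!r}")
        sets.append(_IUPAC[ch])
    return sets


def _count_circular(seq: str, sets: list[str]) -> tuple[int, list[int]]:
    L = len(seq)
    doubled = seq + seq
    positions = []
    m = len(sets)
    for pos in range(L):
        window = doubled[pos : pos + m]
        if all(window[j] in sets[j] for j in range(m)):
            positions.append(pos)
    return len(positions), positions


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a circular sequence preserving its dinucleotide composition.

    The circular sequence defines an Eulerian multigraph on {A,C,G,T} whose
    edges are its wrap-around dinucleotides; a random Eulerian circuit
    (Hierholzer's algorithm over randomly ordered edges) spells a shuffled
    circle with the identical circular dinucleotide multiset.
    """
    L = len(seq)
    succ: dict[str, list[str]] = defaultdict(list)
    for i in range(L):
        succ[seq[i]].append(seq[(i + 1) % L])
    for lst in succ.values():
        order = rng.permutation(len(lst))
        lst[:] = [lst[j] for j in order]
    stack = [seq[0]]
    circuit = []
    while stack:
        v = stack[-1]
        if succ[v]:
            stack.append(succ[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    out = "".join(circuit[:-1])
    if len(out) != L:  # disconnected graph: fall back to the input rotation
        return seq
    return out


def scan_rbp_motifs(
    circ: Union[CircRNA, str],
    motif_table: Mapping[str, str],
    empirical_p: bool = False,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[RBPCount]:
    """Circular IUPAC-motif match counts per RNA-binding protein.

    With ``empirical_p`` the observed count is compared against counts on
    ``n_shuffles`` dinucleotide-shuffled versions of the circle
    (p = (1 + #null >= observed) / (n_shuffles + 1)).
    """
    seq = _seq_of(circ)
    rng = np.random.default_rng(seed)
    out = []
    for name, pattern in motif_table.items():
        sets = _compile_iupac(pattern)
        count, positions = _count_circular(seq, sets)
        p = None
        if empirical_p:
            ge = sum(
                1
                for _ in range(n_shuffles)
                if _count_circular(dinucleotide_shuffle(seq, rng), sets)[0] >= count
            )
            p = (1 + ge) / (n_shuffles + 1)
        out.append(RBPCount(name, pattern, count, positions, p))
    return out
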