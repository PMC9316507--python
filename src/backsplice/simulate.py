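"""Synthetic gene models, circRNAs, and rolling-circle reads.

The generator emulates the kind of locus this toolkit targets: a multi-exon
gene from which circRNAs arise by back-splicing of 2-6 complete or truncated
exons.  Two features of real back-splice junctions are planted explicitly:

* truncation of one or both junction-forming exon ends (novel splice sites
  inside annotated exons), and
* a short identical sequence run (default 3-8 nt) present on both genomic
  sides of the junction, which makes the exact junction placement ambiguous.

Reads model rolling-circle cDNA: each read is a substring of the infinite
rotation of the circle, with i.i.d. substitution errors.  Sanger-style
base-called reads are indel-poor, so the default error model is
substitution-only; an indel rate is exposed as an optional knob.

Every operation is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import json
import numpy as np

from .gene_model import Exon, GeneModel
from .circrna import CircRNA, build_circrna

__all__ = [
    "SimConfig",
    "CircPlan",
    "SimTruth",
    "simulate_gene",
    "simulate_circrna",
    "simulate_reads",
    "write_reads_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic locus and reads."""

    seed: int = 0
    n_exons: int = 10
    exon_length_range: tuple[int, int] = (50, 110)
    intron_length_range: tuple[int, int] = (80, 300)
    gc_fraction: float = 0.5
    n_circ_exons_range: tuple[int, int] = (2, 6)
    truncation_prob: float = 0.8
    truncation_range: tuple[int, int] = (1, 30)
    overlap_homology_range: tuple[int, int] = (3, 8)
    read_error_rate: float = 0.001
    read_indel_rate: float = 0.0
    read_length: int = 700

    def validate(self) -> None:
        for name in ("exon_length_range", "intron_length_range", "truncation_range",
                     "n_circ_exons_range", "overlap_homology_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if self.intron_length_range[0] < 4:
            raise ValueError("introns must be at least 4 nt to carry GT...AG")
        for name in ("gc_fraction", "truncation_prob", "read_error_rate", "read_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CircPlan:
    """Explicit circRNA choice overriding the random sampling.

    ``exon_indices`` in circle order starting at the acceptor (ascending);
    truncations are given as offsets (``acceptor_trunc`` = skipped acceptor
    prefix, ``donor_trunc`` = removed donor suffix).  ``homology`` is the
    identical-run length to plant across the junction (None: sample from the
    config range; 0: enforce an unambiguous junction).
    """

    exon_indices: Sequence[int]
    acceptor_trunc: int = 0
    donor_trunc: int = 0
    homology: Optional[int] = None


@dataclass
class SimTruth:
    """Ground truth for one simulated circRNA.

    ``model`` is the (possibly homology-edited) gene model the circle was cut
    from; annotation must run against this model, since homology planting
    edits the truncated-off exonic regions around the junction.
    """

    exon_indices: list[int]
    acceptor_start_offset: int
    donor_end_offset: int
    acceptor_trunc: int
    donor_trunc: int
    homology_k: int
    homology_left: int
    homology_right: int
    circ_length: int
    model: GeneModel = field(repr=False)

    def to_json(self) -> str:
        doc = {k: v for k, v in asdict(self).items() if k != "model"}
        return json.dumps(doc, sort_keys=True)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def simulate_gene(config: SimConfig, gene_id: str = "synthgene") -> GeneModel:
    """A random multi-exon gene; every intron starts GT and ends AG."""
    config.validate()
    rng = config.rng()
    gc = config.gc_fraction
    parts: list[str] = []
    exons: list[Exon] = []
    pos = 0
    for i in range(1, config.n_exons + 1):
        elen = int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
        eseq = _random_seq(rng, elen, gc)
        exons.append(Exon(index=i, sequence=eseq, genomic_start=pos, genomic_end=pos + elen))
        parts.append(eseq)
        pos += elen
        if i < config.n_exons:
            ilen = int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
            iseq = "GT" + _random_seq(rng, ilen - 4, gc) + "AG"
            parts.append(iseq)
            pos += ilen
    gene_seq = "".join(parts)
    from .gene_model import _flanks_from_gene

    exons = _flanks_from_gene(gene_seq, exons)
    return GeneModel(gene_id=gene_id, exons=exons, gene_sequence=gene_seq)


def _set_base(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1 :]


def _force_mismatch(seq: str, pos: int, other: str, rng: np.random.Generator) -> str:
    """Ensure seq[pos] != other by rewriting seq[pos] if needed."""
    if seq[pos] != other:
        return seq
    choices = [b for b in "ACGT" if b != other]
    return _set_base(seq, pos, choices[int(rng.integers(len(choices)))])


def _rebuild_model(model: GeneModel, gene_seq: str) -> GeneModel:
    from dataclasses import replace

    exons = [
        replace(e, sequence=gene_seq[e.genomic_start : e.genomic_end]) for e in model.exons
    ]
    return GeneModel(gene_id=model.gene_id, exons=exons, gene_sequence=gene_seq)


def simulate_circrna(
    model: GeneModel,
    config: SimConfig,
    plan: Optional[CircPlan] = None,
    rng: Optional[np.random.Generator] = None,
    circ_id: str = "sim_circ",
    plant: bool = True,
) -> tuple[CircRNA, SimTruth]:
    """Cut a circRNA out of the gene, optionally planting junction homology.

    Homology of length ``k`` is planted by editing the *gene* sequence: the
    ``k`` bases flanking the junction are made identical on both genomic
    sides, so that annotator and oracle see a self-consistent locus, while
    the run itself appears only once in the emitted circle.  All edits (and
    the mismatches enforced at both ends of the run, which pin ``k`` exactly)
    fall in the truncated-off exonic regions, so the circle sequence is never
    changed by planting.  Truncation is only ever applied to the two exons
    forming the junction.
    """
    config.validate()
    if rng is None:
        rng = config.rng()

    if plan is None:
        lo, hi = config.n_circ_exons_range
        n_pick = int(rng.integers(lo, min(hi, model.n_exons) + 1))
        first = int(rng.integers(1, model.n_exons - n_pick + 2))
        indices = list(range(first, first + n_pick))
        plan = CircPlan(exon_indices=indices)
        tr_lo, tr_hi = config.truncation_range
        acc_len = len(model.exon(indices[0]))
        don_len = len(model.exon(indices[-1]))
        if rng.random() < config.truncation_prob:
            plan.acceptor_trunc = int(rng.integers(tr_lo, min(tr_hi, acc_len - 1) + 1))
        if rng.random() < config.truncation_prob:
            plan.donor_trunc = int(rng.integers(tr_lo, min(tr_hi, don_len - 1) + 1))
    indices = list(plan.exon_indices)
    acc = model.exon(indices[0])
    don = model.exon(indices[-1])
    if plan.acceptor_trunc >= len(acc) or plan.donor_trunc >= len(don):
        raise ValueError("requested truncation longer than the exon")
    a_start = plan.acceptor_trunc
    d_end = len(don) - plan.donor_trunc
    if len(indices) == 1 and d_end <= a_start:
        raise ValueError("single-exon circle would retain no sequence")

    if not plant:
        # no gene edits: several circles can share one locus.  The realized
        # junction ambiguity is whatever the unedited gene happens to carry.
        circ = build_circrna(model, indices, a_start, d_end, circ_id=circ_id,
                             canonicalize=False)
        truth = SimTruth(
            exon_indices=indices,
            acceptor_start_offset=a_start,
            donor_end_offset=d_end,
            acceptor_trunc=plan.acceptor_trunc,
            donor_trunc=plan.donor_trunc,
            homology_k=circ.bsj.ambiguity_k,
            homology_left=0,
            homology_right=0,
            circ_length=circ.length,
            model=model,
        )
        return circ, truth

    k = plan.homology
    if k is None:
        k_lo, k_hi = config.overlap_homology_range
        k = int(rng.integers(k_lo, k_hi + 1))

    # capacity per side: edits must stay inside the truncated-off exon parts,
    # one base short of the retained boundary (for the enforced mismatch).
    cap_left = max(0, a_start - 1)
    cap_right = max(0, (len(don) - d_end) - 1)
    # the run must also fit inside the retained segments it copies from
    retained_don = d_end - (a_start if len(indices) == 1 else 0)
    retained_acc = (d_end if len(indices) == 1 else len(acc)) - a_start
    cap_left = min(cap_left, retained_don - 1)
    cap_right = min(cap_right, retained_acc - 1)
    k = min(k, cap_left + cap_right)
    k_left = min(cap_left, int(rng.integers(0, k + 1)))
    k_right = min(k - k_left, cap_right)
    k_left = min(k - k_right, cap_left)
    k = k_left + k_right

    gene_seq = model.gene_sequence
    if gene_seq is None:
        raise ValueError("homology planting requires a model with gene_sequence")
    g_acc = acc.genomic_start
    g_don = don.genomic_start
    # left side: bases 5' of the acceptor start copy the retained donor suffix
    for i in range(1, k_left + 1):
        gene_seq = _set_base(gene_seq, g_acc + a_start - i, gene_seq[g_don + d_end - i])
    # right side: bases 3' of the donor end copy the retained acceptor prefix
    for i in range(k_right):
        gene_seq = _set_base(gene_seq, g_don + d_end + i, gene_seq[g_acc + a_start + i])
    # pin the run length: force a mismatch just beyond each end of the run.
    # The rewritten base always sits in a truncated-off region.
    if a_start - k_left - 1 >= 0 and d_end - k_left - 1 >= 0:
        gene_seq = _force_mismatch(
            gene_seq, g_acc + a_start - k_left - 1, gene_seq[g_don + d_end - k_left - 1], rng
        )
    if d_end + k_right < len(don) and a_start + k_right < len(acc):
        gene_seq = _force_mismatch(
            gene_seq, g_don + d_end + k_right, gene_seq[g_acc + a_start + k_right], rng
        )

    edited = _rebuild_model(model, gene_seq)
    circ = build_circrna(
        edited, indices, a_start, d_end, circ_id=circ_id, canonicalize=False
    )
    truth = SimTruth(
        exon_indices=indices,
        acceptor_start_offset=a_start,
        donor_end_offset=d_end,
        acceptor_trunc=plan.acceptor_trunc,
        donor_trunc=plan.donor_trunc,
        homology_k=k,
        homology_left=k_left,
        homology_right=k_right,
        circ_length=circ.length,
        model=edited,
    )
    return circ, truth


@dataclass
class SimRead:
    id: str
    sequence: str
    start: int
    spans_bsj: bool


def _spans_bsj(start: int, read_length: int, circ_length: int) -> bool:
    """True when the read covers both the last and first circle base."""
    first_last = (circ_length - 1 - start) % circ_length
    return first_last + 2 <= read_length


def simulate_reads(
    circ: CircRNA,
    n_reads: int,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[SimRead]:
    """Rolling-circle reads with uniform start and i.i.d. substitutions."""
    config.validate()
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if rng is None:
        rng = config.rng()
    L = circ.length
    rlen = config.read_length
    tiled = circ.sequence * (rlen // L + 2)
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, L))
        seq = tiled[start : start + rlen]
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        if config.read_error_rate > 0:
            hits = np.nonzero(rng.random(rlen) < config.read_error_rate)[0]
            for pos in hits:
                cur = arr[pos]
                alts = _BASES[_BASES != cur]
                arr[pos] = alts[int(rng.integers(3))]
        if config.read_indel_rate > 0:
            out = []
            for pos in range(len(arr)):
                r = rng.random()
                if r < config.read_indel_rate / 2:
                    continue  # deletion
                out.append(arr[pos].decode())
                if r > 1 - config.read_indel_rate / 2:
                    out.append("ACGT"[int(rng.integers(4))])  # insertion
            seq = "".join(out)
        else:
            seq = arr.tobytes().decode()
        spans = _spans_bsj(start, rlen, L)
        rid = f"{circ.id}_read{i:04d}|start={start}|spans_bsj={int(spans)}"
        reads.append(SimRead(id=rid, sequence=seq, start=start, spans_bsj=spans))
    return reads


def write_reads_fasta(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.sequence}\n")
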