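"""Circular RNA records and back-splice-junction geometry.

The back-splice junction (BSJ) joins the 3' end of a downstream ("donor")
exon to the 5' start of an upstream ("acceptor") exon.  Either junction-facing
exon end may be truncated relative to the annotated exon, producing
non-canonical splice boundaries.  When the truncated ends happen to share an
identical sequence run spanning the junction, the exact junction placement is
ambiguous: every shift of the cut point inside that run yields the same
circular sequence.  This module quantifies that ambiguity and fixes one
deterministic canonical placement (ambiguous bases assigned to the donor
side) so that circles can be compared by plain string equality.

Conventions
-----------
* ``donor_end_offset`` — retained length of the donor exon (cut after this
  many bases), in ``(0, len(donor exon)]``.
* ``acceptor_start_offset`` — skipped prefix length of the acceptor exon, in
  ``[0, len(acceptor exon))``.
* The canonical circle sequence starts at the acceptor's first retained base,
  so the BSJ sits between the last and first base of the string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .gene_model import GeneModel, UNKNOWN_FLANK

__all__ = [
    "BackSpliceJunction",
    "CircRNA",
    "build_circrna",
    "compute_overlap_ambiguity",
    "enumerate_junction_placements",
    "canonicalize_offsets",
    "junction_splice_dinucleotides",
    "classify_splice",
]

CANONICAL = "canonical"
NON_CANONICAL = "non_canonical"
UNKNOWN = "unknown"


@dataclass
class BackSpliceJunction:
    donor_exon_index: int
    donor_end_offset: int
    acceptor_exon_index: int
    acceptor_start_offset: int
    donor_truncated: bool = False
    acceptor_truncated: bool = False
    ambiguity_k: int = 0
    ambiguity_string: str = ""
    canonical: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.donor_end_offset <= 0:
            raise ValueError("donor_end_offset must be positive")
        if self.acceptor_start_offset < 0:
            raise ValueError("acceptor_start_offset must be non-negative")
        if len(self.ambiguity_string) != self.ambiguity_k:
            raise ValueError("ambiguity_string length must equal ambiguity_k")


@dataclass
class CircRNA:
    """A circRNA in canonical rotation (sequence starts at the acceptor)."""

    id: str
    segments: list[tuple[int, tuple[int, int]]]  # (exon_index, (start, end)) on the exon
    sequence: str
    bsj: BackSpliceJunction

    def __post_init__(self) -> None:
        seg_len = sum(end - start for _, (start, end) in self.segments)
        if seg_len != len(self.sequence):
            raise ValueError(
                f"segment lengths sum to {seg_len} but sequence has {len(self.sequence)} nt"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def exon_indices(self) -> list[int]:
        return [idx for idx, _ in self.segments]

    def exon_label(self) -> str:
        """Human-readable exon list, truncated BSJ exons marked with ``*``."""
        parts = []
        for i, (idx, _) in enumerate(self.segments):
            star = ""
            if i == 0 and self.bsj.acceptor_truncated:
                star = " *"
            if i == len(self.segments) - 1 and self.bsj.donor_truncated:
                star = " *"
            if len(self.segments) == 1 and (
                self.bsj.acceptor_truncated or self.bsj.donor_truncated
            ):
                star = " *"
            parts.append(f"Exon {idx}{star}")
        return ", ".join(parts)


def build_circrna(
    model: GeneModel,
    exon_indices: Sequence[int],
    acceptor_start_offset: int,
    donor_end_offset: int,
    circ_id: str = "circ",
    canonicalize: bool = True,
) -> CircRNA:
    """Construct the canonical circle for the given exon chain and junction.

    ``exon_indices`` lists the exons in circle order starting at the acceptor
    (ascending gene order); the first is the acceptor, the last the donor.
    Middle exons are complete.  With ``canonicalize`` the junction is first
    shifted to the canonical placement (ambiguous run assigned to the donor).
    """
    indices = list(exon_indices)
    if sorted(set(indices)) != indices:
        raise ValueError(f"exon indices must be strictly ascending, got {indices}")
    acc = model.exon(indices[0])
    don = model.exon(indices[-1])
    single = len(indices) == 1
    if donor_end_offset > len(don):
        raise ValueError(
            f"donor_end_offset {donor_end_offset} exceeds exon {don.index} length {len(don)}"
        )
    if acceptor_start_offset >= len(acc):
        raise ValueError(
            f"acceptor_start_offset {acceptor_start_offset} >= exon {acc.index} length {len(acc)}"
        )
    if single and donor_end_offset <= acceptor_start_offset:
        raise ValueError("single-exon circle would retain no sequence")

    a_start, d_end = acceptor_start_offset, donor_end_offset
    if canonicalize:
        a_start, d_end = canonicalize_offsets(model, indices, a_start, d_end)

    if single:
        segments = [(indices[0], (a_start, d_end))]
        seq = acc.sequence[a_start:d_end]
        donor_trunc = d_end < len(don)
        acceptor_trunc = a_start > 0
    else:
        segments = [(indices[0], (a_start, len(acc)))]
        seq_parts = [acc.sequence[a_start:]]
        for idx in indices[1:-1]:
            exon = model.exon(idx)
            segments.append((idx, (0, len(exon))))
            seq_parts.append(exon.sequence)
        segments.append((indices[-1], (0, d_end)))
        seq_parts.append(don.sequence[:d_end])
        seq = "".join(seq_parts)
        donor_trunc = d_end < len(don)
        acceptor_trunc = a_start > 0

    bsj = BackSpliceJunction(
        donor_exon_index=indices[-1],
        donor_end_offset=d_end,
        acceptor_exon_index=indices[0],
        acceptor_start_offset=a_start,
        donor_truncated=donor_trunc,
        acceptor_truncated=acceptor_trunc,
    )
    k, run, _ = compute_overlap_ambiguity(model, bsj)
    bsj.ambiguity_k = k
    bsj.ambiguity_string = run
    bsj.canonical = classify_splice(model, bsj)
    return CircRNA(id=circ_id, segments=segments, sequence=seq, bsj=bsj)


def _ambiguity_sides(
    model: GeneModel,
    donor_exon_index: int,
    donor_end: int,
    acceptor_exon_index: int,
    acceptor_start: int,
) -> tuple[int, int]:
    """(k_left, k_right) identical-run lengths on either side of the junction.

    ``k_left`` — longest suffix of the retained donor segment equal to the
    exonic bases immediately 5' of the retained acceptor start; ``k_right`` —
    longest prefix of the retained acceptor segment equal to the exonic bases
    immediately 3' of the retained donor end.  Runs are bounded so that every
    shifted junction placement stays inside both exons (the placements
    enumerated by :func:`enumerate_junction_placements`).
    """
    don = model.exon(donor_exon_index)
    acc = model.exon(acceptor_exon_index)

    # shifting left by i: donor_end-i >= 1, acceptor_start-i >= 0
    max_left = min(donor_end - 1, acceptor_start)
    k_left = 0
    while (
        k_left < max_left
        and don.sequence[donor_end - 1 - k_left] == acc.sequence[acceptor_start - 1 - k_left]
    ):
        k_left += 1

    # shifting right by i: donor_end+i <= len(don), acceptor_start+i <= len(acc)-1
    max_right = min(len(don) - donor_end, len(acc) - 1 - acceptor_start)
    k_right = 0
    while (
        k_right < max_right
        and don.sequence[donor_end + k_right] == acc.sequence[acceptor_start + k_right]
    ):
        k_right += 1
    return k_left, k_right


def compute_overlap_ambiguity(
    model: GeneModel, bsj: BackSpliceJunction
) -> tuple[int, str, int]:
    """Junction-overlap ambiguity ``(k, ambiguity_string, n_equivalent_placements)``.

    ``k`` is the length of the identical sequence run spanning the junction
    (0 when the placement is unique); there are always ``k + 1`` equivalent
    junction placements.  The ambiguity string is the junction-spanning run,
    read across the junction in circle orientation.
    """
    k_left, k_right = _ambiguity_sides(
        model,
        bsj.donor_exon_index,
        bsj.donor_end_offset,
        bsj.acceptor_exon_index,
        bsj.acceptor_start_offset,
    )
    don = model.exon(bsj.donor_exon_index)
    acc = model.exon(bsj.acceptor_exon_index)
    run = (
        don.sequence[bsj.donor_end_offset - k_left : bsj.donor_end_offset]
        + acc.sequence[bsj.acceptor_start_offset : bsj.acceptor_start_offset + k_right]
    )
    k = k_left + k_right
    return k, run, k + 1


def canonicalize_offsets(
    model: GeneModel,
    exon_indices: Sequence[int],
    acceptor_start: int,
    donor_end: int,
) -> tuple[int, int]:
    """Shift an ambiguous junction to its canonical placement.

    Among the ``k + 1`` equivalent placements the one with maximal donor
    retention is chosen, i.e. the ambiguous run is assigned to the donor
    (upstream) side of the junction.  Returns the shifted
    ``(acceptor_start, donor_end)``.
    """
    _, k_right = _ambiguity_sides(
        model, exon_indices[-1], donor_end, exon_indices[0], acceptor_start
    )
    return acceptor_start + k_right, donor_end + k_right


def enumerate_junction_placements(
    model: GeneModel,
    exon_indices: Sequence[int],
    acceptor_start: int,
    donor_end: int,
) -> list[tuple[int, int]]:
    """Exhaustive reference for the junction-placement ambiguity.

    Enumerates every valid ``(acceptor_start', donor_end')`` pair producing
    the identical circular molecule — the same sequence up to rotation, since
    cutting the circle at a shifted junction placement rotates its canonical
    string.  Because the circle length is fixed, candidate placements are
    diagonal shifts of the input; this routine nevertheless rebuilds and
    compares the full cyclic sequence for each candidate, making it an
    independent (if slow) check of :func:`compute_overlap_ambiguity`.
    """
    target = build_circrna(
        model, exon_indices, acceptor_start, donor_end, canonicalize=False
    ).sequence
    doubled = target + target
    acc = model.exon(exon_indices[0])
    don = model.exon(exon_indices[-1])
    hits = []
    for a in range(len(acc)):
        d = donor_end + (a - acceptor_start)
        if not 1 <= d <= len(don):
            continue
        if len(exon_indices) == 1 and d <= a:
            continue
        cand = build_circrna(model, exon_indices, a, d, canonicalize=False).sequence
        if len(cand) == len(target) and cand in doubled:
            hits.append((a, d))
    return hits


def junction_splice_dinucleotides(
    model: GeneModel, bsj: BackSpliceJunction
) -> tuple[Optional[str], Optional[str]]:
    """Genomic dinucleotides at the two splice sites forming the BSJ.

    Returns ``(donor_site, acceptor_site)``: the 2 nt immediately 3' of the
    retained donor end and the 2 nt immediately 5' of the retained acceptor
    start.  For a truncated exon end these are exonic bases; for a complete
    exon end they are the intronic flank (``None`` when unknown).
    """
    don = model.exon(bsj.donor_exon_index)
    acc = model.exon(bsj.acceptor_exon_index)

    def _bases_after(exon, offset: int) -> Optional[str]:
        tail = exon.sequence[offset : offset + 2]
        if len(tail) == 2:
            return tail
        flank = exon.donor_flank
        if model.gene_sequence is not None:
            g = exon.genomic_start + offset
            if g + 2 <= len(model.gene_sequence):
                return model.gene_sequence[g : g + 2]
        if flank != UNKNOWN_FLANK:
            return (tail + flank)[:2]
        return None

    def _bases_before(exon, offset: int) -> Optional[str]:
        if offset >= 2:
            return exon.sequence[offset - 2 : offset]
        flank = exon.acceptor_flank
        if model.gene_sequence is not None:
            g = exon.genomic_start + offset
            if g >= 2:
                return model.gene_sequence[g - 2 : g]
        if flank != UNKNOWN_FLANK:
            return (flank + exon.sequence[:offset])[-2:]
        return None

    return _bases_after(don, bsj.donor_end_offset), _bases_before(acc, bsj.acceptor_start_offset)


def classify_splice(model: GeneModel, bsj: BackSpliceJunction) -> str:
    """Classify the BSJ splice sites against the canonical GT/AG rule."""
    donor_site, acceptor_site = junction_splice_dinucleotides(model, bsj)
    if donor_site is None or acceptor_site is None:
        return UNKNOWN
    return CANONICAL if (donor_site == "GT" and acceptor_site == "AG") else NON_CANONICAL
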