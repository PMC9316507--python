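"""Back-splice junction annotation of full-length circRNA reads.

Given a read (for instance a Sanger-derived amplicon sequence) and a gene
model, the annotator

1. collapses rolling-circle reads to roughly one period,
2. finds maximal exon matches by exact k-mer anchor seeding with
   mismatch-tolerant extension (both orientations),
3. chains the matches along the read, allowing exon indices to descend at
   most once — the descent is the back-splice-junction candidate,
4. calls the junction with truncation offsets, quantifies the
   junction-overlap ambiguity, and
5. confirms the read only if the junction is covered with sufficient aligned
   flank on both sides, in which case the circle is reconstructed from the
   *model* sequence (so read errors never leak into the reference circle).

Confirmed circles are deduplicated by canonical-rotation string equality and
catalogued.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel, reverse_complement
from .circrna import (
    BackSpliceJunction,
    CircRNA,
    build_circrna,
    classify_splice,
    compute_overlap_ambiguity,
)

__all__ = [
    "AnnotateParams",
    "SegmentMatch",
    "Chain",
    "AnnotationResult",
    "Catalog",
    "find_exon_matches",
    "chain_segments",
    "call_bsj",
    "confirm_and_reconstruct",
    "annotate_read",
    "dedupe_and_catalog",
    "collapse_rolling_circle",
]


@dataclass
class AnnotateParams:
    """Tunables of the annotator; defaults make error-free recovery exact."""

    min_anchor: int = 18              # exact seed length, nt
    max_mismatch_rate: float = 0.02   # per-base substitution budget in a match
    gap_tol: int = 12                 # max unmatched nt between chained segments
    max_junction_overlap: int = 25    # max read overlap between chained segments
    min_cover_frac: float = 0.75      # chain must cover this fraction of the read
    min_flank: int = 10               # aligned nt required on each side of the BSJ
    min_period: int = 50              # smallest rolling-circle period considered
    period_max_rate: float = 0.05     # mismatch tolerance for period detection


@dataclass(frozen=True)
class SegmentMatch:
    """A maximal match between a read substring and an exon substring."""

    exon_index: int
    read_start: int
    read_end: int
    exon_start: int
    exon_end: int
    mismatches: int
    reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.exon_end - self.exon_start:
            raise ValueError("read and exon interval lengths differ")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass
class Chain:
    segments: list[SegmentMatch]
    descent_index: Optional[int]  # junction between segments[i-1] and segments[i]
    covered: int
    mismatches: int
    reverse_complement: bool


@dataclass
class AnnotationResult:
    read_id: str
    chain: Optional[Chain]
    bsj: Optional[BackSpliceJunction]
    confirmed: bool
    circ: Optional[CircRNA]
    rejection_reason: Optional[str] = None
    collapsed_period: Optional[int] = None


# ---------------------------------------------------------------------------
# rolling-circle collapse
# ---------------------------------------------------------------------------

def collapse_rolling_circle(
    read: str, params: AnnotateParams = AnnotateParams()
) -> tuple[str, Optional[int]]:
    """Collapse a read that traverses the circle more than once.

    The period is the smallest shift under which the read approximately
    matches itself (mismatch fraction <= ``period_max_rate`` over at least 30
    overlapping bases).  The collapsed read keeps the first period plus
    ``2 * (min_anchor + min_flank)`` extra bases: whichever of the two
    junction occurrences in that window falls further from a boundary then
    has at least an anchor-length matchable fragment and the required flank
    on both sides, wherever the rotation happens to start.
    """
    n = len(read)
    min_overlap = 30
    if n < params.min_period + min_overlap:
        return read, None
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    for p in range(params.min_period, n - min_overlap + 1):
        overlap = n - p
        mism = int(np.count_nonzero(arr[:overlap] != arr[p:]))
        if mism <= params.period_max_rate * overlap:
            keep = p + min(overlap, 2 * (params.min_anchor + params.min_flank))
            return read[:keep], p
    return read, None


# ---------------------------------------------------------------------------
# seed-and-extend matching
# ---------------------------------------------------------------------------

def _build_seed_index(model: GeneModel, k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for exon in model.exons:
        seq = exon.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((exon.index, pos))
    return index


def _extend_on_diagonal(
    read: str,
    exon_seq: str,
    seed_rs: int,
    seed_es: int,
    seed_len: int,
    rate: float,
) -> tuple[int, int, int, int, int]:
    """Greedy two-sided extension of an exact seed along one diagonal.

    Mismatches are admitted while the running count stays within one plus
    ``rate * current_length`` (the additive one keeps short segments from
    fragmenting at a single substitution); trailing mismatches are trimmed
    so matches always start and end on agreeing bases.  Returns
    ``(read_start, read_end, exon_start, exon_end, mismatches)``.
    """
    rs, re_ = seed_rs, seed_rs + seed_len
    es, ee = seed_es, seed_es + seed_len
    mism = 0
    mismatch_right: list[int] = []  # read positions of admitted mismatches
    while re_ < len(read) and ee < len(exon_seq):
        if read[re_] == exon_seq[ee]:
            pass
        elif mism + 1 <= 1 + rate * (re_ - rs + 1):
            mismatch_right.append(re_)
            mism += 1
        else:
            break
        re_ += 1
        ee += 1
    mismatch_left: list[int] = []
    while rs > 0 and es > 0:
        if read[rs - 1] == exon_seq[es - 1]:
            pass
        elif mism + 1 <= 1 + rate * (re_ - rs + 1):
            mismatch_left.append(rs - 1)
            mism += 1
        else:
            break
        rs -= 1
        es -= 1
    # trim mismatching ends
    while mismatch_right and mismatch_right[-1] == re_ - 1:
        mismatch_right.pop()
        re_ -= 1
        ee -= 1
        mism -= 1
    while mismatch_left and mismatch_left[-1] == rs:
        mismatch_left.pop()
        rs += 1
        es += 1
        mism -= 1
    return rs, re_, es, ee, mism


def find_exon_matches(
    read: str,
    model: GeneModel,
    params: AnnotateParams = AnnotateParams(),
    both_strands: bool = True,
) -> list[SegmentMatch]:
    """All maximal read-vs-exon matches found by anchor seeding.

    Exact seeds of length ``min_anchor`` are extended in both directions,
    admitting substitutions up to ``max_mismatch_rate``.  With
    ``both_strands`` the reverse complement of the read is scanned too and
    such matches are flagged; their read coordinates refer to the
    reverse-complemented read.
    """
    if not model.exons:
        raise ValueError("empty gene model")
    k = params.min_anchor
    if len(read) < k:
        return []
    index = _build_seed_index(model, k)
    matches: list[SegmentMatch] = []
    orientations = [(read, False)]
    if both_strands:
        orientations.append((reverse_complement(read), True))
    for oriented, is_rc in orientations:
        covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for rpos in range(len(oriented) - k + 1):
            hits = index.get(oriented[rpos : rpos + k])
            if not hits:
                continue
            for exon_idx, epos in hits:
                diag = rpos - epos
                done = covered.setdefault((exon_idx, diag), [])
                if any(s <= rpos and rpos + k <= e for s, e in done):
                    continue
                exon_seq = model.exon(exon_idx).sequence
                rs, re_, es, ee, mism = _extend_on_diagonal(
                    oriented, exon_seq, rpos, epos, k, params.max_mismatch_rate
                )
                done.append((rs, re_))
                matches.append(
                    SegmentMatch(
                        exon_index=exon_idx,
                        read_start=rs,
                        read_end=re_,
                        exon_start=es,
                        exon_end=ee,
                        mismatches=mism,
                        reverse_complement=is_rc,
                    )
                )
    matches.sort(key=lambda m: (m.reverse_complement, m.read_start, m.exon_index))
    return matches


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _transition(
    prev: SegmentMatch, nxt: SegmentMatch, params: AnnotateParams
) -> Optional[str]:
    """Classify a chain transition: 'ascend', 'descend', or None (illegal)."""
    gap = nxt.read_start - prev.read_end
    if gap > params.gap_tol or gap < -params.max_junction_overlap:
        return None
    if nxt.read_start <= prev.read_start or nxt.read_end <= prev.read_end:
        return None
    if nxt.exon_index > prev.exon_index:
        return "ascend"
    if nxt.exon_index == prev.exon_index:
        # continuation within one exon (e.g. a split across a read artefact)
        exon_gap = nxt.exon_start - prev.exon_end
        if -params.max_junction_overlap <= exon_gap <= params.gap_tol and nxt.exon_start > prev.exon_start:
            return "ascend"
        return "descend"
    return "descend"


def chain_segments(
    matches: Sequence[SegmentMatch],
    read_length: int,
    params: AnnotateParams = AnnotateParams(),
) -> Optional[Chain]:
    """Select the best single-descent chain of matches along the read.

    Dynamic programme over matches sorted by read start.  The chain maximises
    covered read bases subject to: consecutive segments nearly adjacent on
    the read (gap <= ``gap_tol``, overlap <= ``max_junction_overlap``), exon
    indices non-decreasing except for at most one descent (the BSJ
    candidate).  Ties break toward fewer mismatches, then fewer segments.
    Returns None when no chain covers ``min_cover_frac`` of the read.
    """
    best_chain: Optional[Chain] = None
    for is_rc in (False, True):
        ms = sorted(
            (m for m in matches if m.reverse_complement == is_rc),
            key=lambda m: (m.read_start, m.read_end),
        )
        if not ms:
            continue
        n = len(ms)
        # dp[(i, d)] = (covered, -mismatches, -count, parent_state)
        dp: dict[tuple[int, int], tuple[int, int, int, Optional[tuple[int, int]]]] = {}
        for i, m in enumerate(ms):
            dp[(i, 0)] = (m.length, -m.mismatches, -1, None)
        for i, m in enumerate(ms):
            for j in range(i):
                t = _transition(ms[j], m, params)
                if t is None:
                    continue
                extra = m.read_end - max(m.read_start, ms[j].read_end)
                for d_prev in (0, 1):
                    if (j, d_prev) not in dp:
                        continue
                    d = d_prev + (1 if t == "descend" else 0)
                    if d > 1:
                        continue
                    cov, negmm, negct, _ = dp[(j, d_prev)]
                    cand = (cov + extra, negmm - m.mismatches, negct - 1, (j, d_prev))
                    if (i, d) not in dp or cand[:3] > dp[(i, d)][:3]:
                        dp[(i, d)] = cand
        # pick the best terminal state
        best_state = None
        best_val = None
        for state, val in dp.items():
            if best_val is None or val[:3] > best_val[:3]:
                best_val = val
                best_state = state
        assert best_state is not None and best_val is not None
        covered = best_val[0]
        if covered < params.min_cover_frac * read_length:
            continue
        # reconstruct
        seq_states = []
        state: Optional[tuple[int, int]] = best_state
        while state is not None:
            seq_states.append(state)
            state = dp[state][3]
        seq_states.reverse()
        segments = [ms[i] for i, _ in seq_states]
        descent_index = None
        for pos in range(1, len(seq_states)):
            if seq_states[pos][1] > seq_states[pos - 1][1]:
                descent_index = pos
                break
        segments, descent_index = _trim_overlaps(segments, descent_index)
        chain = Chain(
            segments=segments,
            descent_index=descent_index,
            covered=covered,
            mismatches=-best_val[1],
            reverse_complement=is_rc,
        )
        if best_chain is None or (chain.covered, -chain.mismatches) > (
            best_chain.covered,
            -best_chain.mismatches,
        ):
            best_chain = chain
    return best_chain


def _trim_overlaps(
    segments: list[SegmentMatch], descent_index: Optional[int]
) -> tuple[list[SegmentMatch], Optional[int]]:
    """Resolve read overlaps between consecutive ascending segments.

    Overlapping bases are assigned to the upstream segment.  The pair at the
    descent is left untouched: its overlap region is the junction-ambiguity
    zone and is resolved by exact re-alignment in :func:`call_bsj`.
    """
    out: list[SegmentMatch] = []
    new_descent = descent_index
    for i, seg in enumerate(segments):
        if out and i != descent_index and seg.read_start < out[-1].read_end:
            o = out[-1].read_end - seg.read_start
            if o >= seg.length:
                if descent_index is not None and i < descent_index:
                    new_descent -= 1
                continue
            seg = replace(
                seg,
                read_start=seg.read_start + o,
                exon_start=seg.exon_start + o,
            )
        out.append(seg)
    return out, new_descent


# ---------------------------------------------------------------------------
# junction calling and confirmation
# ---------------------------------------------------------------------------

def _refine_junction(
    read: str,
    donor_seg: SegmentMatch,
    acceptor_seg: SegmentMatch,
    model: GeneModel,
) -> tuple[int, int]:
    """Exact re-alignment of the junction split point.

    The greedy extensions of the donor and acceptor matches may overlap (the
    donor extends into the acceptor's bases wherever the genomic sides of the
    junction agree — the ambiguity run — or past an admitted mismatch) or
    leave a small gap (errors trimmed near the junction).  This scans every
    split position in that window and keeps the one with the fewest total
    mismatches against the model; ties resolve toward maximal donor
    retention, which is the canonical placement of an ambiguous junction.
    Returns ``(donor_end_offset, acceptor_start_offset)``.
    """
    don_seq = model.exon(donor_seg.exon_index).sequence
    acc_seq = model.exon(acceptor_seg.exon_index).sequence
    d_rs, d_es = donor_seg.read_start, donor_seg.exon_start
    a_rs, a_es = acceptor_seg.read_start, acceptor_seg.exon_start
    w0 = min(a_rs, donor_seg.read_end)
    w1 = max(a_rs, donor_seg.read_end)
    q_min = max(d_rs + 1, a_rs - a_es, w0)
    q_max = min(
        d_rs + (len(don_seq) - d_es),
        a_rs + (len(acc_seq) - 1 - a_es),
        w1,
    )
    if q_min > q_max:
        return donor_seg.exon_end, acceptor_seg.exon_start
    best_q, best_mism = None, None
    for q in range(q_min, q_max + 1):
        mism = 0
        for pos in range(w0, q):
            if read[pos] != don_seq[d_es + pos - d_rs]:
                mism += 1
        for pos in range(q, w1):
            if read[pos] != acc_seq[a_es + pos - a_rs]:
                mism += 1
        if best_mism is None or mism <= best_mism:
            best_q, best_mism = q, mism
    return d_es + (best_q - d_rs), a_es + (best_q - a_rs)


def call_bsj(
    chain: Chain, model: GeneModel, read: Optional[str] = None
) -> Optional[BackSpliceJunction]:
    """Call the back-splice junction at the chain's single descent.

    When the (orientation-matched) read is supplied, the junction placement
    is re-aligned exactly within the overlap/gap window between the donor and
    acceptor matches; otherwise the match endpoints are trusted as-is.
    """
    if chain.descent_index is None:
        return None
    donor_seg = chain.segments[chain.descent_index - 1]
    acceptor_seg = chain.segments[chain.descent_index]
    don = model.exon(donor_seg.exon_index)
    if read is not None:
        donor_end, acceptor_start = _refine_junction(read, donor_seg, acceptor_seg, model)
    else:
        donor_end, acceptor_start = donor_seg.exon_end, acceptor_seg.exon_start
    bsj = BackSpliceJunction(
        donor_exon_index=donor_seg.exon_index,
        donor_end_offset=donor_end,
        acceptor_exon_index=acceptor_seg.exon_index,
        acceptor_start_offset=acceptor_start,
        donor_truncated=donor_end < len(don),
        acceptor_truncated=acceptor_start > 0,
    )
    k, run, _ = compute_overlap_ambiguity(model, bsj)
    bsj.ambiguity_k = k
    bsj.ambiguity_string = run
    bsj.canonical = classify_splice(model, bsj)
    return bsj


def confirm_and_reconstruct(
    read_id: str,
    chain: Optional[Chain],
    model: GeneModel,
    params: AnnotateParams = AnnotateParams(),
    collapsed_period: Optional[int] = None,
    read: Optional[str] = None,
) -> AnnotationResult:
    """Apply the confirmation rule and reconstruct the reference circle.

    A read is confirmed only when its chain covers the junction with at least
    ``min_flank`` aligned nt on each side.  The emitted circle is rebuilt
    from the model exon sequences at the canonical junction placement, in
    canonical rotation (starting at the acceptor's first retained base).
    """
    if chain is None:
        return AnnotationResult(
            read_id, None, None, False, None, rejection_reason="unannotatable",
            collapsed_period=collapsed_period,
        )
    bsj = call_bsj(chain, model, read=read)
    if bsj is None:
        return AnnotationResult(
            read_id, chain, None, False, None,
            rejection_reason="no junction evidence",
            collapsed_period=collapsed_period,
        )
    d = chain.descent_index
    flank_before = sum(s.length for s in chain.segments[:d])
    flank_after = sum(s.length for s in chain.segments[d:])
    if flank_before < params.min_flank or flank_after < params.min_flank:
        return AnnotationResult(
            read_id, chain, bsj, False, None,
            rejection_reason="insufficient junction flank",
            collapsed_period=collapsed_period,
        )
    indices = sorted({s.exon_index for s in chain.segments})
    if indices[0] != bsj.acceptor_exon_index or indices[-1] != bsj.donor_exon_index:
        return AnnotationResult(
            read_id, chain, bsj, False, None,
            rejection_reason="inconsistent exon chain around junction",
            collapsed_period=collapsed_period,
        )
    try:
        circ = build_circrna(
            model,
            indices,
            bsj.acceptor_start_offset,
            bsj.donor_end_offset,
            circ_id=read_id,
            canonicalize=True,
        )
    except ValueError as exc:
        return AnnotationResult(
            read_id, chain, bsj, False, None,
            rejection_reason=f"reconstruction failed: {exc}",
            collapsed_period=collapsed_period,
        )
    return AnnotationResult(
        read_id, chain, circ.bsj, True, circ, collapsed_period=collapsed_period
    )


def annotate_read(
    read: str,
    model: GeneModel,
    read_id: str = "read",
    params: AnnotateParams = AnnotateParams(),
) -> AnnotationResult:
    """Full annotation of one read: collapse, match, chain, call, confirm."""
    collapsed, period = collapse_rolling_circle(read, params)
    matches = find_exon_matches(collapsed, model, params)
    chain = chain_segments(matches, len(collapsed), params)
    oriented = collapsed
    if chain is not None and chain.reverse_complement:
        oriented = reverse_complement(collapsed)
    return confirm_and_reconstruct(
        read_id, chain, model, params, collapsed_period=period, read=oriented
    )


# ---------------------------------------------------------------------------
# cataloguing
# ---------------------------------------------------------------------------

@dataclass
class Catalog:
    """Deduplicated circRNA catalog with per-circle support counts."""

    circrnas: list[CircRNA]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.circrnas)


def dedupe_and_catalog(
    circs: Sequence[CircRNA],
    samples: Optional[Sequence[str]] = None,
    id_prefix: str = "circ",
) -> Catalog:
    """Merge circles identical under rotation-invariant sequence equality.

    Circles are already in canonical rotation, so equality reduces to plain
    string comparison.  Catalog rows carry id, supporting sample labels,
    exon count, exon list with truncation asterisks, and length.
    """
    if samples is not None and len(samples) != len(circs):
        raise ValueError("samples must align with circs")
    groups: dict[str, dict] = {}
    for i, circ in enumerate(circs):
        entry = groups.setdefault(
            circ.sequence,
            {"circ": circ, "support": 0, "samples": [], "read_ids": []},
        )
        entry["support"] += 1
        entry["read_ids"].append(circ.id)
        if samples is not None and samples[i] not in entry["samples"]:
            entry["samples"].append(samples[i])
    rows = []
    unique: list[CircRNA] = []
    for n, entry in enumerate(groups.values(), start=1):
        circ: CircRNA = entry["circ"]
        circ = replace(circ, id=f"{id_prefix}-{n}")
        unique.append(circ)
        rows.append(
            {
                "circ_id": circ.id,
                "samples": "; ".join(entry["samples"]),
                "n_reads": entry["support"],
                "exon_count": len(circ.segments),
                "exons": circ.exon_label(),
                "length_nt": circ.length,
                "ambiguity_k": circ.bsj.ambiguity_k,
                "splice": circ.bsj.canonical,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "circ_id", "samples", "n_reads", "exon_count",
            "exons", "length_nt", "ambiguity_k", "splice",
        ],
    )
    return Catalog(circrnas=unique, table=table)
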