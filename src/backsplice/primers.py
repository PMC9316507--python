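"""Divergent primer design and in-silico PCR on circular templates.

Divergent (outward-facing) primer pairs sit inside a single exon: the
reverse primer near the exon 5' end pointing upstream, the forward primer
near the 3' end pointing downstream.  On the linear gene they can never
converge, so they yield no product; on a circular template containing the
exon the synthesis paths wrap around the back-splice junction and converge,
producing a junction-spanning amplicon.  A second, inner pair (nested: both
primers replaced; semi-nested: one reused) raises specificity on a
first-round product.

Melting temperatures use a nearest-neighbor thermodynamic model with the
unified duplex parameters of SantaLucia (1998): 25 nM of each strand,
50 mM monovalent salt, entropy salt correction 0.368 * (N-1) * ln[Na+].
A simple Wallace-rule estimate is available as a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .gene_model import GeneModel, clean_sequence, reverse_complement
from .circrna import CircRNA

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "AmpliconPrediction",
    "PrimerDesignError",
    "design_divergent_pair",
    "design_second_round",
    "predict_amplicon",
    "predict_amplicon_linear",
    "tm_and_gc",
]


class PrimerDesignError(RuntimeError):
    """No primer pair satisfies the binding constraints."""


@dataclass
class PrimerConstraints:
    length: tuple[int, int] = (18, 25)
    gc: tuple[float, float] = (0.40, 0.60)
    tm: tuple[float, float] = (57.0, 63.0)


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    target_exon_index: int
    forward_start: int      # 0-based half-open positions on the exon
    forward_end: int
    reverse_start: int
    reverse_end: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    round: str = "first"    # first | nested | semi_nested

    def __post_init__(self) -> None:
        if self.forward_start < self.reverse_end and self.round == "first":
            raise ValueError(
                "divergent pair: forward primer must lie 3' of the reverse primer"
            )


@dataclass
class AmpliconPrediction:
    circ_id: str
    product_sequence: str
    product_length: int
    spans_bsj: bool


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

# SantaLucia (1998) unified nearest-neighbor parameters:
# delta-H kcal/mol, delta-S cal/(mol K), 5'->3' top-strand dinucleotides.
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_R_GAS = 1.987  # cal/(mol K)
_DNAC1_NM = 25.0
_DNAC2_NM = 25.0
_NA_MM = 50.0


def tm_and_gc(primer: str, wallace: bool = False) -> tuple[float, float]:
    """Melting temperature (degrees C) and GC fraction of a primer.

    Nearest-neighbor Tm under the module's documented default conditions,
    or the Wallace rule (2 degrees per A/T, 4 per G/C) when requested.
    """
    seq = clean_sequence(primer, context="primer")
    if len(seq) < 8:
        raise ValueError(f"primer too short ({len(seq)} nt < 8)")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if wallace:
        tm = 2.0 * (seq.count("A") + seq.count("T")) + 4.0 * (seq.count("G") + seq.count("C"))
        return tm, gc
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = _INIT[term]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    if seq == reverse_complement(seq):
        ds += -1.4
        conc = _DNAC1_NM * 1e-9
    else:
        conc = (_DNAC1_NM - _DNAC2_NM / 2) * 1e-9
    ds += 0.368 * (len(seq) - 1) * math.log(_NA_MM * 1e-3)
    tm = dh * 1000.0 / (ds + _R_GAS * math.log(conc)) - 273.15
    return tm, gc


# ---------------------------------------------------------------------------
# candidate search
# ---------------------------------------------------------------------------

def _occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def _is_unique(model: GeneModel, primer: str) -> bool:
    """True when the primer binds exactly one site in the whole gene model."""
    space = model.gene_sequence or "".join(e.sequence for e in model.exons)
    return _occurrences(space, primer) + _occurrences(space, reverse_complement(primer)) == 1


@dataclass
class _Candidate:
    start: int
    end: int
    seq: str
    tm: float
    gc: float


def _candidates(
    model: GeneModel,
    exon_index: int,
    window: tuple[int, int],
    constraints: PrimerConstraints,
    orientation: str,
    stats: dict[str, int],
) -> list[_Candidate]:
    """Constraint-passing primer candidates whose exon footprint is in window."""
    exon_seq = model.exon(exon_index).sequence
    lo, hi = window
    out = []
    for length in range(constraints.length[0], constraints.length[1] + 1):
        for start in range(lo, hi - length + 1):
            site = exon_seq[start : start + length]
            primer = site if orientation == "forward" else reverse_complement(site)
            tm, gc = tm_and_gc(primer)
            if not constraints.gc[0] <= gc <= constraints.gc[1]:
                stats["gc"] += 1
                continue
            if not constraints.tm[0] <= tm <= constraints.tm[1]:
                stats["tm"] += 1
                continue
            if not _is_unique(model, primer):
                stats["uniqueness"] += 1
                continue
            out.append(_Candidate(start, start + length, primer, tm, gc))
    return out


def _best_pair(
    rev: list[_Candidate], fwd: list[_Candidate], top: int = 30
) -> Optional[tuple[_Candidate, _Candidate]]:
    """Non-overlapping (reverse, forward) pair with the best Tm balance."""
    mid = lambda cs: sorted(cs, key=lambda c: abs(c.tm - 60.0))[:top]
    best = None
    for r in mid(rev):
        for f in mid(fwd):
            if f.start < r.end:
                continue
            key = abs(f.tm - r.tm)
            if best is None or key < best[0]:
                best = (key, r, f)
    if best is None:
        return None
    return best[1], best[2]


def design_divergent_pair(
    model: GeneModel,
    exon_index: int,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> PrimerPair:
    """Design an outward-facing pair on one exon.

    The reverse primer is drawn from the 5' portion of the exon and the
    forward primer from the 3' portion, without overlap, each unique in the
    gene model, maximising Tm balance within the length/GC/Tm constraints.
    """
    exon = model.exon(exon_index)
    if len(exon) < 2 * constraints.length[0]:
        raise PrimerDesignError(
            f"exon {exon_index} ({len(exon)} nt) too short to host two "
            f"non-overlapping {constraints.length[0]}-nt primers"
        )
    stats = {"gc": 0, "tm": 0, "uniqueness": 0}
    half = len(exon) // 2
    rev = _candidates(model, exon_index, (0, half), constraints, "reverse", stats)
    fwd = _candidates(model, exon_index, (half, len(exon)), constraints, "forward", stats)
    pair = _best_pair(rev, fwd)
    if pair is None:
        raise PrimerDesignError(
            f"no divergent pair on exon {exon_index} satisfies the constraints "
            f"(rejected: {stats['gc']} GC, {stats['tm']} Tm, "
            f"{stats['uniqueness']} uniqueness; "
            f"{len(rev)} reverse x {len(fwd)} forward candidates left)"
        )
    r, f = pair
    return PrimerPair(
        forward=f.seq,
        reverse=r.seq,
        target_exon_index=exon_index,
        forward_start=f.start,
        forward_end=f.end,
        reverse_start=r.start,
        reverse_end=r.end,
        tm_forward=f.tm,
        tm_reverse=r.tm,
        gc_forward=f.gc,
        gc_reverse=r.gc,
        round="first",
    )


def design_second_round(
    first: PrimerPair,
    model: GeneModel,
    mode: str = "nested",
    constraints: PrimerConstraints = PrimerConstraints(),
) -> PrimerPair:
    """Design the inner second-round pair for nested or semi-nested PCR.

    Nested: both primers strictly interior to the first-round amplicon.
    Semi-nested: the first-round forward primer is reused and only the
    reverse primer moves inward (interior reverse failing that, the forward
    moves inward instead and the reverse is reused).
    """
    if mode not in ("nested", "semi_nested"):
        raise ValueError(f"mode must be 'nested' or 'semi_nested', got {mode!r}")
    exon_index = first.target_exon_index
    exon = model.exon(exon_index)
    stats = {"gc": 0, "tm": 0, "uniqueness": 0}
    # first-round product runs exon[forward_start:] --BSJ--> exon[:reverse_end],
    # so interior windows shrink from both product ends.
    inner_fwd_window = (first.forward_start + 1, len(exon))
    inner_rev_window = (0, first.reverse_end - 1)
    fwd = _candidates(model, exon_index, inner_fwd_window, constraints, "forward", stats)
    rev = _candidates(model, exon_index, inner_rev_window, constraints, "reverse", stats)
    f_cand = r_cand = None
    if mode == "nested":
        pair = _best_pair(rev, fwd)
        if pair is None:
            raise PrimerDesignError(
                f"first-round product interior on exon {exon_index} too short "
                f"for a nested pair (rejected: {stats})"
            )
        r_cand, f_cand = pair
    else:
        reused_f = _Candidate(first.forward_start, first.forward_end,
                              first.forward, first.tm_forward, first.gc_forward)
        reused_r = _Candidate(first.reverse_start, first.reverse_end,
                              first.reverse, first.tm_reverse, first.gc_reverse)
        pair = _best_pair(rev, [reused_f])
        if pair is None:
            pair = _best_pair([reused_r], fwd)
        if pair is None:
            raise PrimerDesignError(
                f"no interior primer on exon {exon_index} for semi-nested PCR "
                f"(rejected: {stats})"
            )
        r_cand, f_cand = pair
    return PrimerPair(
        forward=f_cand.seq,
        reverse=r_cand.seq,
        target_exon_index=exon_index,
        forward_start=f_cand.start,
        forward_end=f_cand.end,
        reverse_start=r_cand.start,
        reverse_end=r_cand.end,
        tm_forward=f_cand.tm,
        tm_reverse=r_cand.tm,
        gc_forward=f_cand.gc,
        gc_reverse=r_cand.gc,
        round=mode,
    )


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return out
        out.append(pos)
        start = pos + 1


def predict_amplicon(circ: CircRNA, pair: PrimerPair) -> Optional[AmpliconPrediction]:
    """In-silico PCR of a divergent pair on a circular template.

    Scans the doubled circle for perfect forward and reverse-complemented
    reverse primer sites and reports the shortest product no longer than one
    full period.  Returns None when either primer has no perfect site.
    """
    seq = circ.sequence
    L = len(seq)
    doubled = seq + seq
    f_sites = [p for p in _find_all(doubled, pair.forward) if p < L]
    r_rc = reverse_complement(pair.reverse)
    r_ends = [p + len(r_rc) for p in _find_all(doubled, r_rc)]
    best: Optional[tuple[int, int]] = None
    for pf in f_sites:
        for re_ in r_ends:
            if re_ - len(r_rc) < pf + len(pair.forward):
                continue  # primers must not overlap in the product
            if re_ - pf > L:
                continue  # longer than one period
            if best is None or re_ - pf < best[1] - best[0]:
                best = (pf, re_)
    if best is None:
        return None
    pf, re_ = best
    return AmpliconPrediction(
        circ_id=circ.id,
        product_sequence=doubled[pf:re_],
        product_length=re_ - pf,
        spans_bsj=re_ > L,
    )


def predict_amplicon_linear(template: str, pair: PrimerPair) -> Optional[AmpliconPrediction]:
    """In-silico PCR on a linear template (no wrap-around).

    Divergent pairs cannot converge on a line, so this returns None for any
    correctly designed pair on its own gene; it exists to verify exactly
    that specificity.
    """
    f_sites = _find_all(template, pair.forward)
    r_rc = reverse_complement(pair.reverse)
    r_ends = [p + len(r_rc) for p in _find_all(template, r_rc)]
    best = None
    for pf in f_sites:
        for re_ in r_ends:
            if re_ - len(r_rc) < pf + len(pair.forward):
                continue
            if best is None or re_ - pf < best[1] - best[0]:
                best = (pf, re_)
    if best is None:
        return None
    pf, re_ = best
    return AmpliconPrediction(
        circ_id="linear",
        product_sequence=template[pf:re_],
        product_length=re_ - pf,
        spans_bsj=False,
    )
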