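"""Back-splice junction annotation: matching, chaining, calling, recovery."""

import pytest

from backsplice.annotate import (
    AnnotateParams,
    annotate_read,
    chain_segments,
    collapse_rolling_circle,
    confirm_and_reconstruct,
    dedupe_and_catalog,
    find_exon_matches,
)
from backsplice.circrna import build_circrna
from backsplice.gene_model import reverse_complement
from backsplice.simulate import CircPlan, SimConfig, simulate_circrna, simulate_gene, simulate_reads


def _truth_circle(truth):
    return build_circrna(
        truth.model,
        truth.exon_indices,
        truth.acceptor_start_offset,
        truth.donor_end_offset,
        canonicalize=True,
    )


# ---------------------------------------------------------------------------
# find_exon_matches
# ---------------------------------------------------------------------------

def test_exact_exon_read_matches_whole_read(gene):
    read = gene.exon(4).sequence
    matches = [m for m in find_exon_matches(read, gene) if not m.reverse_complement]
    full = [m for m in matches if m.exon_index == 4]
    assert len(full) == 1
    m = full[0]
    assert (m.read_start, m.read_end) == (0, len(read))
    assert (m.exon_start, m.exon_end) == (0, len(read))
    assert m.mismatches == 0


def test_two_exon_read_with_one_substitution(gene):
    e5, e6 = gene.exon(5).sequence, gene.exon(6).sequence
    mutated = list(e6)
    pos = len(e6) // 2
    mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
    read = e5 + "".join(mutated)
    matches = [m for m in find_exon_matches(read, gene) if not m.reverse_complement]
    m5 = [m for m in matches if m.exon_index == 5]
    m6 = [m for m in matches if m.exon_index == 6]
    assert any(m.exon_start == 0 and m.exon_end == len(e5) for m in m5)
    # the exon-6 match crosses the substitution and reports it
    assert any(m.exon_start == 0 and m.exon_end == len(e6) and m.mismatches == 1
               for m in m6)


def test_random_foreign_sequence_yields_no_match(gene):
    import numpy as np

    rng = np.random.default_rng(5)
    k = AnnotateParams().min_anchor
    space = gene.gene_sequence
    while True:
        probe = "".join(rng.choice(list("ACGT"), size=50))
        # oracle scan: accept the probe only if no anchor-length window occurs
        windows = {probe[i : i + k] for i in range(len(probe) - k + 1)}
        windows |= {reverse_complement(probe)[i : i + k] for i in range(len(probe) - k + 1)}
        if not any(w in space for w in windows):
            break
    assert find_exon_matches(probe, gene) == []


def test_reverse_complement_reads_are_flagged(gene):
    read = reverse_complement(gene.exon(4).sequence)
    matches = find_exon_matches(read, gene)
    assert any(m.reverse_complement and m.exon_index == 4 for m in matches)


def test_empty_model_rejected(gene):
    import dataclasses

    with pytest.raises(Exception):
        find_exon_matches("ACGT" * 20, dataclasses.replace(gene, exons=[]))


# ---------------------------------------------------------------------------
# chaining and junction calling
# ---------------------------------------------------------------------------

def test_single_exon_read_chains_without_descent(gene):
    read = gene.exon(4).sequence
    matches = find_exon_matches(read, gene)
    chain = chain_segments(matches, len(read))
    assert chain is not None
    assert chain.descent_index is None
    assert [s.exon_index for s in chain.segments] == [4]
    result = confirm_and_reconstruct("r", chain, gene, read=read)
    assert not result.confirmed
    assert result.rejection_reason == "no junction evidence"


def test_chain_has_single_descent_at_wraparound(gene, default_config):
    """A read from a circle rotates the exon order; the one descent in the
    chained exon indices marks the junction."""
    plan = CircPlan(exon_indices=[4, 5, 6, 7], homology=0)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    # start the read inside exon 6: order on read is 6,7 | 4,5,6-prefix
    start = sum(e - s for _, (s, e) in circ.segments[:2]) + 10
    read = (circ.sequence * 2)[start : start + circ.length]
    matches = find_exon_matches(read, truth.model)
    chain = chain_segments(matches, len(read))
    idx = [s.exon_index for s in chain.segments]
    descents = [i for i in range(1, len(idx)) if idx[i] < idx[i - 1]]
    assert chain.descent_index is not None
    assert descents == [chain.descent_index]
    assert idx[chain.descent_index - 1] == 7 and idx[chain.descent_index] == 4


def test_single_exon_circle_calls_degenerate_junction(gene):
    """A full single-exon circle: donor == acceptor with offsets at bounds."""
    exon = gene.exon(6)
    circ = build_circrna(gene, [6], acceptor_start_offset=0, donor_end_offset=len(exon))
    read = (circ.sequence * 2)[25 : 25 + circ.length]
    result = annotate_read(read, gene)
    assert result.confirmed
    bsj = result.bsj
    assert bsj.donor_exon_index == bsj.acceptor_exon_index == 6
    assert bsj.acceptor_start_offset == 0 and bsj.donor_end_offset == len(exon)


@pytest.mark.parametrize("acc_trunc,don_trunc", [(1, 1), (30, 30), (17, 4), (0, 25)])
def test_truncation_offsets_recovered(gene, default_config, acc_trunc, don_trunc):
    plan = CircPlan(exon_indices=[4, 5, 6], acceptor_trunc=acc_trunc,
                    donor_trunc=don_trunc, homology=0)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    read = (circ.sequence * 2)[: circ.length + 40]
    result = annotate_read(read, truth.model)
    assert result.confirmed
    assert result.bsj.acceptor_start_offset == truth.acceptor_start_offset
    assert result.bsj.donor_end_offset == truth.donor_end_offset
    assert result.bsj.acceptor_truncated == (acc_trunc > 0)
    assert result.bsj.donor_truncated == (don_trunc > 0)


def test_error_free_simulations_recover_truth_exactly():
    """annotate -> confirm -> reconstruct reproduces the planted circle
    (composition, offsets modulo placement equivalence, length) every time."""
    ok = 0
    n = 60
    for seed in range(n):
        cfg = SimConfig(seed=seed, read_error_rate=0.0)
        model = simulate_gene(cfg)
        circ, truth = simulate_circrna(model, cfg)
        read = simulate_reads(circ, 1, cfg)[0]
        result = annotate_read(read.sequence, truth.model, read_id=read.id)
        expected = _truth_circle(truth)
        if (
            result.confirmed
            and result.circ.sequence == expected.sequence
            and result.circ.exon_indices == truth.exon_indices
            and result.circ.length == truth.circ_length
        ):
            ok += 1
    assert ok == n


def test_rotation_invariance_of_canonical_reconstruction(gene, default_config):
    """Reads starting anywhere on the circle reconstruct the same circle."""
    plan = CircPlan(exon_indices=[5, 6, 7], acceptor_trunc=9, donor_trunc=13, homology=4)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    tiled = circ.sequence * 3
    sequences = set()
    for r in range(0, circ.length, 23):
        read = tiled[r : r + circ.length + 40]
        result = annotate_read(read, truth.model)
        assert result.confirmed, r
        sequences.add(result.circ.sequence)
    assert len(sequences) == 1


def test_read_inside_single_exon_rejected(gene):
    read = gene.exon(6).sequence
    result = annotate_read(read, gene)
    assert not result.confirmed
    assert result.rejection_reason == "no junction evidence"


def test_reconstruction_uses_model_not_read(gene, default_config):
    """Substitution errors in the read never leak into the emitted circle."""
    plan = CircPlan(exon_indices=[4, 5, 6], homology=0)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    read = list((circ.sequence * 2)[: circ.length + 40])
    read[circ.length // 2] = "A" if read[circ.length // 2] != "A" else "G"
    result = annotate_read("".join(read), truth.model)
    assert result.confirmed
    assert result.circ.sequence == _truth_circle(truth).sequence


def test_collapse_detects_rolling_circle_period(gene, default_config):
    plan = CircPlan(exon_indices=[5, 6], homology=0)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    read = (circ.sequence * 4)[: 3 * circ.length]
    collapsed, period = collapse_rolling_circle(read)
    assert period == circ.length
    assert len(collapsed) < len(read)


def test_noise_tolerant_junction_recovery():
    """At 0.5% substitution noise, nearly all junction-spanning reads still
    yield the planted junction."""
    ok = tot = 0
    for seed in range(20):
        cfg = SimConfig(seed=seed, read_error_rate=0.005)
        model = simulate_gene(cfg)
        circ, truth = simulate_circrna(model, cfg)
        expected = _truth_circle(truth)
        for read in simulate_reads(circ, 5, cfg):
            tot += 1
            result = annotate_read(read.sequence, truth.model)
            if result.confirmed and result.circ.sequence == expected.sequence:
                ok += 1
    assert tot == 100
    assert ok / tot >= 0.95


# ---------------------------------------------------------------------------
# dedupe / catalog
# ---------------------------------------------------------------------------

def test_rotated_reads_merge_to_one_catalog_entry(gene, default_config):
    plan = CircPlan(exon_indices=[5, 6], acceptor_trunc=8, homology=3)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    doubled = circ.sequence * 2
    circles = []
    for r in (0, 57, 113):
        result = annotate_read(doubled[r : r + circ.length + 40], truth.model,
                               read_id=f"read{r}")
        assert result.confirmed
        circles.append(result.circ)
    catalog = dedupe_and_catalog(circles, samples=["s1", "s1", "s2"])
    assert len(catalog) == 1
    row = catalog.table.iloc[0]
    assert row["n_reads"] == 3
    assert row["samples"] == "s1; s2"
    assert row["length_nt"] == circ.length


def test_catalog_counts_distinct_simulated_circles():
    cfg = SimConfig(seed=3)
    model = simulate_gene(cfg)
    rng = cfg.rng()
    circles = []
    truth_seqs = set()
    for i in range(50):
        circ, truth = simulate_circrna(model, cfg, rng=rng, plant=False,
                                       circ_id=f"c{i}")
        canon = build_circrna(truth.model, truth.exon_indices,
                              truth.acceptor_start_offset,
                              truth.donor_end_offset, canonicalize=True)
        truth_seqs.add(canon.sequence)
        circles.append(canon)
    circles += circles[::2]  # shuffled duplicates
    catalog = dedupe_and_catalog(circles)
    assert len(catalog) == len(truth_seqs)


def test_catalog_exon_labels_mark_truncations(gene, default_config):
    plan = CircPlan(exon_indices=[5, 6], acceptor_trunc=11, homology=0)
    circ, truth = simulate_circrna(gene, default_config, plan=plan)
    catalog = dedupe_and_catalog([_truth_circle(truth)])
    assert catalog.table.iloc[0]["exons"] == "Exon 5 *, Exon 6"
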