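# Methods

## Coordinate and sequence conventions

All coordinates are 0-based half-open on transcript-oriented sequences;
exon indices are 1-based ("Exon 1 … Exon 10"), matching how annotated loci
are discussed. Minus-strand input is reverse-complemented once at load
time, so every algorithm downstream is strand-free. Sequences are stored
as uppercase DNA (RNA `U` → `T` on input); motif and context strings in
feature reports are rendered back as RNA, as they read on the transcript.

A back-splice junction (BSJ) is parameterized by the **donor end offset**
(retained length of the downstream exon, in `(0, len]`) and the **acceptor
start offset** (skipped prefix of the upstream exon, in `[0, len)`).
The canonical circle rotation starts at the acceptor's first retained
base, which turns rotation-invariant deduplication into plain string
equality.

## Junction-overlap ambiguity

When the truncated ends forming the junction share an identical sequence
run, the junction placement is not unique: shifting the cut point inside
the run yields the same circular molecule. We measure the run as
`k = k_left + k_right`, where `k_left` is the longest suffix of the
retained donor segment equal to the exonic bases immediately 5′ of the
retained acceptor start, and `k_right` the longest prefix of the retained
acceptor segment equal to the exonic bases immediately 3′ of the retained
donor end. Each comparison is bounded so that every shifted placement
keeps both offsets inside their exons; under that bound the number of
equivalent placements is exactly `k + 1`, and
`enumerate_junction_placements` — which rebuilds and compares the full
cyclic sequence of every candidate placement — is kept in the package
purely as an independent cross-check of the efficient measure. We restrict
the comparison to exonic bases (rather than letting the run continue into
an intron) because an intron-reaching run would correspond to placements
that are not valid exonic junctions, breaking the `k + 1` law; empirically
the observed runs sit inside the exons in any case.

Because the assignment of the run to either exon is undecidable from
sequence alone, the catalog stores `k` and the run itself, and reports one
deterministic **canonical placement**: the run assigned entirely to the
donor (upstream) side, i.e. the equivalent placement with maximal donor
retention.

## Annotation algorithm

1. **Rolling-circle collapse.** The period is the smallest shift `p` under
   which the read matches itself with mismatch fraction ≤ 5% over ≥ 30
   overlapping bases (vectorized byte comparison). The collapsed read
   keeps `p + 2·(min_anchor + min_flank)` bases: of the two junction
   occurrences inside that window, at least one has an anchor-length
   matchable fragment and the required flank on both sides, wherever the
   rotation started.
2. **Seed and extend.** Exact `min_anchor`-mers (default 18 nt) of the
   read are looked up in a per-exon k-mer index and extended greedily on
   their diagonal. Mismatches are admitted while the running count stays
   within `1 + max_mismatch_rate · length` (default rate 2%); the additive
   1 keeps short exon segments from fragmenting at a single substitution.
   Trailing mismatches are trimmed so matches start and end on agreeing
   bases. Both orientations are scanned; reverse-complement matches are
   flagged and chained separately.
3. **Chaining.** A dynamic programme selects the chain of matches
   maximizing covered read bases, with consecutive segments nearly
   adjacent on the read (gap ≤ `gap_tol`, default 12 nt; overlap ≤
   `max_junction_overlap`, default 25 nt) and exon indices non-decreasing
   except for at most one descent. Ties break toward fewer mismatches,
   then fewer segments. Chains covering < 75% of the collapsed read are
   rejected as unannotatable.
4. **Junction refinement.** Greedy extensions overlap across the junction
   wherever the genomic sides agree (the ambiguity run) and can slip past
   an admitted mismatch, so match endpoints are not trusted: every split
   position in the overlap/gap window between the donor and acceptor
   matches is scored by total mismatches against the model, and ties
   resolve toward maximal donor retention — which is exactly the canonical
   ambiguity convention, so error-free reads land on the canonical
   placement directly.
5. **Confirmation and reconstruction.** A read is confirmed only when its
   chain covers the junction with ≥ `min_flank` (default 10) aligned nt on
   each side; otherwise it is rejected with reason `no junction evidence`
   (or `insufficient junction flank`). Confirmed circles are rebuilt from
   the model exon sequences at the canonical placement, so substitution
   errors in reads cannot enter the catalog. The splice classification
   compares the dinucleotides just outside the retained ends (exonic bases
   for truncated ends, intronic flanks for complete ends) against GT/AG;
   models without introns yield `unknown` rather than a guess.

Defaults were chosen so that error-free recovery of simulated circles is
exact while 0.5%-substitution reads still recover the planted junction in
≥ 95% of cases; all are exposed on `AnnotateParams`. The gap tolerance
(12 nt) is deliberately larger than a naive adjacency bound: a clustered
pair of substitutions near a splice boundary trims up to ~10 nt from the
flanking matches, and interior gaps are harmless because middle exons are
reconstructed complete from the model.

## Synthetic data: what it emulates, and what it does not

`simulate_gene` draws a multi-exon gene (default 10 exons of 50–110 nt,
introns 80–300 nt beginning `GT` and ending `AG`, GC 0.5). Exon lengths
emulate a locus whose circRNAs of 2–6 exons span roughly 200–550 nt, so a
default 700-nt read always covers at least one full period. Circles
truncate only the two junction-forming exons (offsets 1–30 nt, each end
with probability 0.8), mirroring junctions that create novel splice sites
inside annotated exons.

Junction homology (default 3–8 nt, the observed span) is **planted by
editing the gene**, not the circle: the `k` bases flanking the junction
are copied so they are identical on both genomic sides, and a mismatch is
forced just beyond each end of the run to pin `k` exactly. All edits fall
in the truncated-off exonic regions, so the emitted circle sequence is
provably unchanged and the run appears once in the circle. Because the
edits are genomic, the generator returns the edited model inside
`SimTruth`; annotation must run against it. When several circles share one
gene (the pipeline's multi-circle simulation), planting is disabled so the
circles' loci cannot edit each other's retained bases, and the realized
ambiguity is whatever the unedited gene carries.

Reads model rolling-circle cDNA: uniform start, substitution errors i.i.d.
at the configured rate (default 0.1%, Sanger-like), optional indel rate
(default 0, since base-called Sanger reads are indel-poor). The generator
does **not** model chromatogram noise, PCR amplification bias, chimeric
templates, or intron-retaining circles — passing tests therefore
demonstrate correctness of the annotation logic under clean rolling-circle
assumptions, not robustness to every artefact of real trace data.

## Primer design and thermodynamics

Divergent pairs are drawn from a single exon: reverse-primer candidates
from its 5′ half, forward candidates from its 3′ half, lengths 18–25 nt,
GC 40–60%, Tm 57–63 °C (all configurable), each primer required to have a
unique perfect-match site in the whole gene model; among admissible
non-overlapping pairs the one with minimal |ΔTm| wins. Nested pairs are
re-designed strictly inside the first-round product; semi-nested pairs
reuse exactly one first-round primer. In-silico PCR is perfect-match only
(the verification use-case; a 3′-mismatch binding model is future work)
and reports the shortest single-period product on the doubled circle.

Tm uses the unified nearest-neighbor parameters of SantaLucia (1998) with
25 nM of each strand, 50 mM monovalent salt, and the `0.368·(N−1)·ln[Na+]`
entropy correction; a Wallace-rule estimate is available behind a flag.
The constants are documented module constants, and the test suite checks
the implementation against an independently maintained nearest-neighbor
implementation to within 1 °C.

## Feature scanning on circles

**ORFs.** Three modes reflect how a linear-only ORF tool must treat a
circle. The two linearized modes cut at the BSJ or at the adjacent splice
site and scan three forward frames, reporting per frame the 5′-most ATG of
each stop-delimited segment (ORFs reaching the cut end carry
`stop_found=False`). The circular mode scans every ATG on the circle and
translates across the junction; it reports *every* qualifying start rather
than the 5′-most per stop segment, because a circular frame cycle may
contain no stop at all, making "first ATG after a stop" ill-defined — this
also makes the superset law (circular ⊇ both linearized modes, on start
positions) exact. ORFs that meet no in-frame stop within one extra period
are capped at `L/3` codons and flagged. "More than 50 amino acids" is
interpreted strictly as ≥ 51 residues, stop codon excluded.

**miRNA seed sites** follow the canonical taxonomy: 8mer = reverse
complement of miRNA positions 2–8 followed by an A opposite position 1;
7mer-m8 drops the A; 7mer-A1 pairs positions 2–7 plus the A. The best
class is reported per position. **m⁶A** uses the DRACH consensus (D∈AGU,
R∈AG, A, C, H∈ACU) centered on each adenosine, an explicit simplification
relative to learned m⁶A models — only consensus membership of a context is
asserted, never a prediction score. **RBP motifs** are IUPAC patterns
counted circularly, with an optional empirical p-value against
dinucleotide-shuffled circles (random Eulerian circuits over the
dinucleotide transition multigraph, default 1000 shuffles). External
predictors' numerical scores (miRNA prediction scores, RBP weighted-rank
Z-scores, learned m⁶A scores) are out of scope by design; the packaged
tables carry them only as fixture metadata.

All circular scans run on the doubled (or tripled) sequence with start
positions restricted to one period, so the ambiguity bases at the junction
are counted exactly once.

## Problem sizes and determinism

The shipped verification (`scripts/acceptance.py` and the test suite) uses
500 seeded instances for the ambiguity-oracle comparison, 200 error-free
simulations and 1000 noisy reads for round-trip recovery, 100 genes for
primer specificity, and 500 circles for the ORF superset law — sizes at
which every stochastic rate estimate is stable to well under a percentage
point between seeds. Every random stream derives from a single integer
seed; identical configurations produce byte-identical FASTA/TSV/JSON
outputs.

## Known limitations

* Exonic circles only: intron-retaining circRNAs and inter-genic fusions
  are not modelled.
* One gene model at a time; no genome-scale search (short-read BSJ
  detection à la CIRI/CIRCexplorer is a non-goal).
* Perfect-match primer binding; no dimer/hairpin thermodynamic screening.
* The read model is substitution-dominated; heavy indel noise (raw
  chromatogram artefacts) will fragment anchors and lower recovery.
* Junction ambiguity is measured within exonic sequence; a hypothetical
  identical run continuing into an intron is truncated at the exon edge.
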