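# backsplice

Tooling for discovering and characterizing **full-length circular RNAs
(circRNAs)** from divergent-primer amplicon sequencing, built around the
dry-lab half of a circRNA discovery workflow: design outward-facing primer
pairs that amplify only circular templates, annotate the resulting
full-length (Sanger-style) reads against a gene model, call the
**back-splice junction (BSJ)** with truncation offsets and
junction-overlap ambiguity, and characterize each confirmed circle
(circular ORFs, miRNA seed sites, m⁶A DRACH sites, RBP motif counts).

It is aimed at molecular biologists validating circRNAs of a single gene —
the setting in which nine novel circRNAs of the human *PRMT1* gene
(GenBank ON081037–ON081045) were characterized — and at method developers
who need a seeded generator of circRNA ground truth.

## The problem and the model

A circRNA arises by back-splicing: a downstream splice **donor** joins an
upstream splice **acceptor**, closing the transcript into a circle of 2–6
complete or truncated exons. Full-length annotation of a read `r` against a
gene model proceeds as:

1. **Rolling-circle collapse** — a cDNA read can traverse the circle more
   than once; the smallest approximate self-overlap period is detected and
   the read is collapsed to roughly one period.
2. **Anchor seeding** — maximal read-vs-exon matches from exact `k`-mer
   seeds (default 18 nt) with mismatch-tolerant extension.
3. **Single-descent chaining** — the chain of matches maximizing covered
   read bases in which exon indices are non-decreasing except at most one
   *descent*; that descent is the BSJ candidate.
4. **Junction calling** — exact re-alignment of the split point around the
   descent; the junction is reported with donor/acceptor truncation offsets
   and classified against the canonical GT/AG rule.
5. **Overlap ambiguity** — when the two genomic sides of the junction share
   an identical run of `k` bases (observed spans: 3–8 nt), the junction has
   exactly `k + 1` indistinguishable placements. The run length, its
   sequence, and a deterministic canonical placement (run assigned to the
   donor side) are recorded; a brute-force placement enumeration is kept as
   an independent oracle.
6. **Confirmation** — a read confirms a circRNA only if its chain covers
   the BSJ with sufficient aligned flank on both sides; the reference
   circle is then rebuilt from the *model* sequence, so read errors never
   leak into the catalog. Circles identical up to rotation are merged.

Divergent primers face outward on the linear gene (reverse primer near the
exon 5′ end, forward near the 3′ end) and therefore converge — and
amplify — only on a circular template; in-silico PCR on the doubled circle
verifies that every designed pair yields no product on the linear gene and
a BSJ-spanning product on any circle containing the target exon.

## Worked example

Simulate a ten-exon gene with five planted circRNAs and three error-free
reads each, then annotate:

```
$ backsplice simulate --seed 1 --error-rate 0 --out sim
wrote 15 reads from 5 circles to sim
$ backsplice annotate --bed sim/gene.bed --fasta sim/gene.fa \
      --reads sim/reads.fa --out catalog.tsv
15 reads -> 5 circRNAs (catalog.tsv)
$ cat catalog.tsv
circ_id  samples  n_reads  exon_count  exons                                             length_nt  ambiguity_k  splice
circ-1            3        4           Exon 4, Exon 5, Exon 6, Exon 7 *                  308        0            non_canonical
circ-2            3        6           Exon 3, Exon 4, Exon 5, Exon 6, Exon 7, Exon 8 *  502        0            non_canonical
circ-3            3        6           Exon 4 *, Exon 5, Exon 6, Exon 7, Exon 8, Exon 9 *  482      2            non_canonical
circ-4            3        4           Exon 7 *, Exon 8, Exon 9, Exon 10 *               342        1            non_canonical
circ-5            3        2           Exon 3 *, Exon 4                                  192        0            non_canonical
```

All five planted circles are recovered with their exon composition (a `*`
marks a truncated junction-forming exon), length, and junction-overlap
ambiguity `k`. `circ-3` has `k = 2`: two bases flanking its junction are
identical on both genomic sides, so three junction placements are
equivalent and the catalog stores the canonical one.

The packaged worked-example tables (the nine-circRNA catalog and its
top-two predicted sponged miRNAs) are summarized by:

```
$ backsplice report
{
 "n_circrnas": 9,
 "exon_occurrences": {"1": 3, "3": 3, "4": 6, "5": 7, "6": 8, "7": 7, "8": 3, "9": 1, "10": 1},
 "most_frequent_exon": 6,
 "most_frequent_exon_count": 8,
 "min_length_nt": 204,
 "max_length_nt": 551
}
{
 "miR-494-3p": 7,
 "miR-6754-3p": 6,
 ...
}
```

Exon 6 appears in eight of the nine circRNAs; lengths run from 204 to
551 nt; seven circles carry top-scoring seed sites for miR-494-3p and six
for miR-6754-3p.

From Python, the same objects are available directly:

```python
from backsplice import SimConfig, simulate_gene, design_divergent_pair

model = simulate_gene(SimConfig(seed=19, exon_length_range=(140, 200)))
pair = design_divergent_pair(model, 4)
print(pair.forward, pair.reverse, round(pair.tm_forward, 1))
# GCTGGCCTCGTCAGACGCTACATAA GTGCAGCCCTAACGCGTATGAGAGA 60.6
```

## Scope notes

The toolkit deliberately re-implements interaction scanning as transparent
primitives (TargetScan-style seed classes, the DRACH consensus, IUPAC
motif counts) rather than reproducing the scores of external prediction
services, and it models exonic circRNAs only — see `docs/methods.md` for
assumptions, parameter defaults, and limitations.
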