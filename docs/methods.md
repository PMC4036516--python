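# Methods

This note documents the statistical procedures implemented in `auxrescan`,
the parameters that matter, the design choices made where the procedure was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Promoter definition

A gene's promoter is the window of at most `max_len` (default 1000) bases
immediately 5′ of the first base of its start codon, on the coding strand.
The window stops early at the first base covered by **any other gene's
span, on either strand** — the most conservative reading of "non-coding
upstream sequence" — or at the chromosome edge. Minus-strand windows are
reverse-complemented so every promoter reads 5′→3′ relative to its gene.
Genes whose start codon abuts a neighbour get a length-0 promoter; these
are carried through reporting but excluded from the denominator when
cohorts are summarised. Truncation provenance (which gene clipped the
window) is recorded; clipping by the chromosome edge is not flagged as
truncation. Internally all coordinates are 0-based half-open; GFF3/FASTA
I/O converts at the boundary. When a gene has several mRNAs the one with
the longest total CDS is the representative model. N bases are kept in
promoter sequences and count as mismatches during scanning.

## AuxRE pair statistic

The motif set defaults to the three AuxRE hexamers `TGTCGG`, `TGTCGA`,
`TGTCTC`. An **occurrence** is a 6-mer window on either strand of the
promoter whose Hamming distance to a motif (or to its reverse complement,
for the − strand) is at most `max_mismatch` (default 1). Occurrences are
identified by (start, strand, motif): a window within one mismatch of both
`TGTCGG` and `TGTCGA` (which are themselves Hamming distance 1 apart)
yields two occurrences.

A **pair** is an unordered couple of distinct, non-overlapping occurrences
whose inter-motif gap — end of the first 6-mer to start of the second — is
at most `window` (default 20) bases. Pairs may mix strands and motifs; an
occurrence may participate in any number of pairs; the six pair classes are
the unordered motif-name combinations (3 same + 3 mixed). Two occurrences
sharing the same window never pair (the non-overlap rule), so the
double-match above does not create a self-pair. Configurable alternatives:
`distance_mode="start"` (start-to-start distance) and
`require_nonoverlap=False`; both default to the literal reading described
here.

Consequence worth knowing: because occurrences can be multiply matched and
multiply paired, the per-promoter total pair count is **heavily
right-tailed** — a chance cluster of k occurrence positions within one
window contributes up to 4·C(k,2) pairs. This drives the power analysis
below.

## Shuffle null

Each promoter is tested against its own composition-matched null: the
sequence's characters are permuted uniformly (`n_shuffles` = 100, matching
standard practice for this test) and the total pair count is recomputed on
each shuffle. The report per promoter:

- `null_mean`, `null_sd` — mean and **population** (divide-by-n) standard
  deviation of the shuffle counts; they summarise a fixed set of values,
  not a sample from a larger one;
- `fraction_fewer` — the fraction of shuffles with **strictly** fewer total
  pairs than the real sequence; ties count against significance, so a
  promoter with zero real pairs can never be significant;
- `significant` — `fraction_fewer ≥ significance_fraction` (default 0.95).

One judgment is made per promoter on the aggregate count across all six
pair classes; per-class actual counts are reported alongside. Each promoter
draws from its own RNG stream seeded by (master seed, SHA-256 of the
promoter id), so results are independent of processing order and
reproducible to the bit. A dinucleotide-preserving shuffle
(Altschul–Erickson random Eulerian path) is available as an option; the
default mononucleotide shuffle matches the composition-preserving null the
test was designed around. The hot path is vectorised (all shuffles of a
promoter are scanned as one integer matrix); it is exercised against the
scalar path in the test suite.

## Read counting and RPKM

A read (possibly multiple alignment records sharing a read id) targets
every gene whose exon model overlaps any aligned block by at least
`min_overlap` (default 1) base — this implements counting reads that only
partially cover a UTR. If the read targets between 1 and `max_targets`
(default 20) distinct genes it contributes a full count of 1 to each; past
the cap it contributes nothing, but still counts toward the mapped-read
total. The strand bucket (sense/antisense) compares read strand and gene
strand under a required `orientation` flag (`forward`: read on the gene's
strand is sense; `reverse`: the dUTP convention). RPKM uses the merged exon
length of the representative model and the total reads mapped to the
genome, including gene-free reads. Fractional multimapper weighting is
deliberately not the default — each in-cap target gets a full 1.

## DE intersection and enrichment

Genes are "shared DE" when adjusted *P* is strictly below alpha (default
0.05) in **both** comparisons; direction is taken from the first table with
a conflict flag when the second disagrees. Enrichment of a gene set within
each functional category is the upper-tail hypergeometric probability
P(X ≥ k) with population N (the explicit gene universe), K category genes,
n set genes, k overlap — computed by exact pmf summation (scipy), never a
normal approximation — followed by Benjamini–Hochberg adjustment applied
separately per tested gene set (statsmodels). Several gene sets (e.g.
all/common/unique splits) can be tested against one map in a single call.
Categories are tested independently without overlap correction, as per-bin
testing implies. Category genes outside the universe are logged and dropped
from K; the universe itself is explicit user input because it changes every
frequency in the output.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline consumes, with ground
truth:

- **Genomes/annotations** — genes laid on one chromosome with intergenic
  gaps drawn so that a configurable fraction (default 0.25) of genes has a
  neighbour within 1 kb, exercising promoter truncation; 1–2 exons per
  gene, 0–100 nt 5′ UTRs.
- **Promoter cohorts** — i.i.d. bases at the default composition
  A/C/G/T = 0.33/0.17/0.17/0.33 (66% AT, the AT-rich composition typical
  of the solanaceous genomes this analysis targets). A `signal_fraction`
  (default 0.1) of promoters receives `planted_pairs_per_signal_gene`
  (default 2) motif pairs at gap `planted_gap` (default 10 ≤ 20), written
  in place at random offsets in disjoint segments.
- **DE tables** — generated at the adjusted-P level directly (the DE model
  itself is out of scope): exactly `n_de_shared` genes significant in both
  tables, plus per-table unique genes and optional boundary genes at
  exactly alpha (excluded by the strict rule).
- **Category maps** — 136 categories by default; planted enriched
  categories sample members with odds 10 on DE genes and draw sizes 15–30
  (a size-5 category cannot carry detectable enrichment at these odds, so
  planted categories use the upper size range; background categories span
  5–30).
- **Alignments** — per-gene unique reads, multimappers at degrees including
  exactly 20 and 21 to probe both sides of the cap, and intergenic reads
  that map to the genome but no gene.

Not emulated: real tomato sequence structure (repeats, TA microsatellites,
CpG/composition heterogeneity along the promoter), negative-binomial count
noise, sequencing error, or isoform structure. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
stated generative model, not performance on real genomes, where promoter
composition heterogeneity will make the shuffle null anti-conservative for
repeat-rich promoters (the dinucleotide shuffle option mitigates this).

## Power of the 0.95 rule, and a known limitation

On pure background the rule is conservative by construction (ties count
against significance): measured false-call fractions on 1000 background
promoters are ~0.03–0.06, inside the binomial band around 0.05.

Recovery of planted pairs is limited by the right tail of the null. With
two planted pairs in 300-nt promoters, a planted promoter's own null
(which shuffles the planted motif bases too) occasionally recreates
occurrence clusters with large pair counts, so promoters whose planted
motifs drew the weaker hexamers sit at exact tail probabilities of
0.03–0.10, and with only 100 shuffles the significance call on those is
near a coin flip. Measured sensitivity at the default conditions is
~0.75–0.85 with false-positive rate ~0.04–0.06; the asymptotic (exact-tail)
ceiling is ~0.82 at the default composition. Raising `n_shuffles` removes
the discreteness noise but not the ceiling; the ceiling itself is a
property of the pair statistic's multiply-matched, multiply-paired counting
rules. Users wanting higher power on short promoters should use more
shuffles and consider `max_mismatch=0`.

## Numerical and reproducibility choices

- Problem sizes in tests and the acceptance script (cohorts of 686–1000
  promoters, 100–10,000 shuffles, 12-nt exhaustive enumerations) were
  chosen so every check runs comfortably on one CPU.
- Sequence encoding is A=0, C=1, G=2, T=3, N=4; N mismatches everything.
- `fraction_fewer` and all summaries are plain counts over the shuffle set;
  no continuity corrections.
- Hypergeometric tails are validated to 1e-12 against exact rational
  enumeration for all N ≤ 12; BH against longhand step-up computation.
- All RNG is numpy `default_rng`; cohort work derives one stream per
  promoter from (seed, id-hash) so parallel or reordered execution cannot
  change results.
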