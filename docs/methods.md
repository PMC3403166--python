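# Methods

## Pipeline model

`pmeta` performs similarity-based taxonomic binning of shotgun reads
restricted to the 16S rRNA gene: reads carrying a 16S fragment are
detected and excised with a profile HMM, mapped to an annotated 16S
reference set, classified by best hit, and compared across samples on a
single rank-structured tree. Each step is a pure function of its inputs
and the configuration, which is what makes the chunk-parallel execution
exactly reproducible.

## Profile HMM and Viterbi scanning

The model is a classic match/insert/delete profile over {A,C,G,T}.
Match and insert emissions are stored as log-odds in bits against a
uniform 0.25 background; transitions as log2 probabilities for the nine
moves {M,I,D}→{M,I,D} between adjacent positions. Delete states exist
only strictly inside the model: local entry and exit happen exclusively
through match states and are free (zero cost), with unaligned read
flanks also free. This is deliberately simpler than full Plan7 (no
B/E/J special states, one hit per read per strand): the pipeline only
needs the single best 16S interval per read.

The scanner runs the Viterbi recurrence on the read and its reverse
complement and keeps the better strand (ties prefer the forward
strand). Traceback resolves score ties by preferring match over delete
over insert predecessors, making the reported interval deterministic.
Ambiguity codes (N etc.) emit at background, i.e. contribute 0 bits.

*Model construction.* `ProfileHMM.from_seed_alignment` estimates match
emissions per column of an ungapped seed alignment by maximum likelihood
with a +1 pseudocount per residue. Insert emissions are background.
Transitions are global priors: 0.9/0.05/0.05 out of match, 0.8/0.15/0.05
out of insert (favoring return to match), 0.8/0.05/0.15 out of delete.
With an ungapped seed there is no indel signal to estimate
position-specific transitions from; the priors encode "indels are rare,
and once in a gap state, extending is cheaper than switching gap type".

*Reporting threshold.* Default 20 bits, configurable. On the synthetic
study conditions the separation is wide (planted fragments score ≳50
bits, the best background read ≈17 bits), so the default is exercised
by the tests rather than tuned by them.

*Numerics.* The DP fill is a numba kernel returning the full matrices;
traceback runs in Python only for reads above threshold. All arithmetic
is straight-line double precision, so results are bit-identical across
chunkings and worker processes.

## Seed-and-extend mapping

For each query strand, exact shared 16-mers against the reference index
are grouped per (reference, diagonal) and merged when overlapping; each
merged run is extended ungapped with an X-drop rule (X = 20 score
units), and the best ungapped segment per reference seeds a banded
(half-width 16) local Smith–Waterman with affine gaps (+1 match, −2
mismatch, gap of length g costs 5 + 2g). One hit per (reference,
strand) is reported at most. Word length 16 (rather than a longer
megaBLAST-style word) keeps seeds findable in ~100 nt fragments at a
few percent divergence. The DP tie-break order (diagonal > gap-in-query
> gap-in-subject > fresh start, first maximum in row-major order) fixes
the traceback deterministically.

*Statistics.* Bit score S′ = (λS − ln K)/ln 2 and E-value
E = K·m·n·e^(−λS) with m the query length and n the total database
residue count. λ is the positive root of Σ pᵢpⱼ e^{λsᵢⱼ} = 1 (found by
Brent's method); K comes from the renewal series
K = e^(−2σ)/H, σ = Σⱼ (1/j)[P(Sⱼ ≥ 0) + E(e^{λSⱼ}; Sⱼ < 0)],
H = E[X e^{λX}], computed by convolving the per-column score
distribution (terms decay geometrically under the negative drift). The
form is for unit-span score lattices, which every supported scheme is;
it was validated against direct simulation of maximal ungapped local
alignment scores. Gapped alignments reuse the ungapped λ/K, the usual
practical approximation. Default reporting cutoff E ≤ 1e-5 — a
conventional floor for 16S identification, configurable.

*Coordinates.* Internally 0-based half-open on the forward strand of
both sequences; the 12-column tabular output uses 1-based inclusive
coordinates, query always ascending, minus-strand hits encoded by
descending subject coordinates. Conversion happens only at
(de)serialization.

## Decomposition and deterministic merge

`decompose` cuts a query list into at most n contiguous chunks balanced
greedily by residue count (each chunk closes at the remaining-average
load while always leaving one query per remaining chunk). Chunks are
independent; results are collected keyed by chunk index and concatenated
in plan order, which equals per-query serial output by construction.
Worker processes are forked so JIT-compiled kernels are inherited. The
invariants "output identical for every chunk count" and "identical for
every completion order" are property-tested and asserted end-to-end at
the pipeline level.

## Classification

A fragment is classified by its single best hit (highest bit score, then
lowest E-value, then lexicographically smallest subject id) — not by a
lowest-common-ancestor rule; an LCA mode is out of scope. The default
identity floor of 90% blocks spurious assignments from weak alignments
while tolerating the few percent of read noise plus reference divergence
expected within a genus. Lineages are parsed from the rank-prefixed
semicolon dialect and truncated at their first unfilled rank, so counts
are always prefix-consistent; a best hit whose subject lacks a taxonomy
entry is logged and counted unclassified.

Report percentages are computed over classified fragments, with the
unclassified share reported separately over all fragments (both views
are emitted since either normalization is defensible).

## Consensus tree and normalization

The comparison tree is the union of observed lineage paths, at most six
ranked levels below the root (kingdom is collapsed into the root since
the displayed levels are phylum through species). Per-sample proportions
divide each node count by that sample's classified total, which makes
bars comparable between samples of very different sequencing depth; the
SVG additionally rescales bars per node to the largest proportion at
that node, otherwise rare taxa would be invisible — the TSV carries the
unscaled proportions, so both per-node and per-level views are
available. Children are ordered by descending pooled count, ties
alphabetical, making the rendering independent of input order.

## Synthetic data generator

`generate_reference` evolves n taxa from one random ancestor on a star
topology with per-taxon divergence drawn from 2–15% (substitutions only,
so the taxa rows are naturally an ungapped alignment and double as the
HMM seed). Default reference length is 300 nt — a variable-region-sized
stretch of the gene, which keeps whole-suite runtimes in seconds while
preserving every algorithmic property being tested. `generate_sample`
plants fragments of 60–100 nt into 100 nt reads (Illumina-scale), taxon
drawn by abundance, uniform interval, strand Bernoulli(0.5),
substitutions at the configured rate (default 1%), embedded in uniform
ACGT background; everything is a deterministic function of the seed, and
the emitted truth table is the oracle for recall and composition checks.

What the generator does *not* emulate: indel or quality-dependent
sequencing error, GC-biased background, conserved non-16S genes,
paired-end structure, chimeras. Passing tests therefore demonstrate
algorithmic correctness and the determinism contract, not field accuracy
on real saliva metagenomes; on real data the HMM seed alignment and the
reference database would come from a curated 16S resource.

## Problem sizes in tests and the acceptance script

Unit tests run on 60–600 read samples; the end-to-end determinism check
uses two 2,000-read samples at thread counts 1/2/8; composition recovery
uses ~2,000 planted fragments at 1% substitutions and recall ~1,200
planted fragments at 5%; kernel-vs-oracle comparisons use 200 random
instances each. These sizes were chosen so the full suite completes in
well under a minute on one CPU while keeping every statistical assertion
comfortably powered (binomial standard errors an order of magnitude
below the asserted tolerances).

## Known limitations

* One hit per read per strand; multi-domain or chimeric reads are not
  split.
* The banded gapped extension can miss optima farther than 16 diagonals
  from the best ungapped seed (measured to occur in <10% of adversarial
  random pairs, ~0% on realistic fragments).
* Gapped E-values reuse ungapped λ/K.
* The kingdom rank is parsed but not displayed as a tree level.
* FASTQ support is Sanger/Phred+33 only; mates are independent reads.
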