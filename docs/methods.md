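# Methods

`phagesv` reimplements, as a tested library, an analysis workflow for
structural variation (SV) in phage genomes: consensus merging of
multi-caller SV callsets, construction of a cohort-level nonredundant SV
set, and a collection of downstream analyses that ask whether phage SVs
carry sequence exchanged with bacteria. Every stage can be driven from
a bundled synthetic-cohort generator whose ground truth makes each stage
scoreable end to end.

## Coordinates and SV intervals

All coordinates are 0-based and half-open internally; the 1-based VCF
convention is converted only at the I/O boundary. Every SV — insertions
included — has the effective interval `[start, start + length)`, so all
four types (INS, DEL, DUP, INV) flow through the same interval
arithmetic. Deletion `SVLEN` is normalised to its absolute value on
read. Read support is taken from INFO `RE`, then INFO `SUPPORT`, then
FORMAT `DV` (first match wins; absent means 0): callers disagree on
where they report depth, and this cascade covers the common long-read
callers without configuration.

## Reference prefiltering (MinHash / Mash)

Before SV calling, each sample is compared with the genome catalogue so
that reads are only mapped to genomes actually present. Genomes and
sample constituents are reduced to bottom-`s` MinHash sketches of
canonical k-mers (`k = 21`, `s = 1000`, the standard Mash defaults); the
Mash distance is

    d = -(1/k) * ln(2j / (1 + j)),

with `j` the Jaccard index estimated from the bottom-`s` of the merged
hash union, capped at 1 when the sketches are disjoint. Genomes within
`d <= 0.10` of the sample (≈ 90% identity, since Mash distance
approximates per-base divergence) are retained. The hash is a
splitmix64 finalizer over the 2-bit-packed canonical k-mer, salted with
a fixed version constant, so sketches are portable across runs and
platforms; `k` is kept odd so no k-mer is its own reverse complement.
The end-to-end pipeline sketches each assembled sample constituent
separately and retains a catalogue genome if any constituent is within
the cut: a pooled whole-sample sketch would conflate containment with
similarity (a genome fully present in a diverse sample still has a tiny
Jaccard index against the pooled k-mer set).

On 10–100 kb pairs at 0–10% divergence the sketch distance stays within
0.02 of the distance computed from the exact Jaccard of the full
canonical k-mer sets (tested; the binomial sampling error at `s = 1000`
bounds it).

## Consensus merging (CAST)

Within a sample, calls are partitioned by (contig, type), then into
non-overlapping coordinate groups (connected components of the ≥ 1 bp
interval-overlap relation). Inside a group, two calls are connected
when their mutual (reciprocal) overlap — intersection length divided by
the longer call's length — is at least 0.8. Because positional jitter
between callers deletes edges, this graph is a *corrupted clique* graph,
and it is clustered with the Cluster Affinity Search Technique (CAST)
at affinity threshold `t = 0.5`:

* open a cluster with the maximum-degree unassigned node;
* repeatedly add the unassigned node of highest affinity (edge count
  into the cluster) while that affinity is ≥ `t·|C|`;
* then repeatedly remove the member of lowest affinity while it is
  below `t·|C|`;
* close when neither phase changes anything.

All ties break deterministically on (start, length, caller-priority
rank, record id), which makes the merge invariant to input order. A
singleton cluster closes rather than evicting its own seed (with binary
edges and `t ≤ 1` the removal rule taken literally would empty it). An
iteration cap guards against add/remove oscillation; it is never
reached in practice. The implementation is checked against a naive
transliteration of the same rules on random graphs.

Clusters survive when they contain calls from ≥ 2 distinct callers and
their representative — the member from the highest-priority caller
(Sniffles > cuteSV > pbsv > SVIM, the callers' benchmark order) — has
read support ≥ 2, length > 50 bp (strict), and sits ≥ 100 bp from both
contig ends. Filters are applied to the representative because the
representative is the reported SV. Cross-sample merging pools
per-sample representatives through the same machinery; the cohort
representative is the member whose call recurs (overlap ≥ 0.8) in the
most samples — the most prevalent call in the population.

## Benchmarking against an implanted truth set

A call matches a truth SV when contig and type agree, the start
positions are within 500 bp, and the length ratio is ≥ 0.7 (a common
SV-comparison parameterisation; both are configurable). Matching is
one-to-one: a greedy pass consumes eligible pairs by ascending start
distance (ties: length difference, then ids), and a deterministic
augmenting-path pass then extends the result to maximum bipartite
cardinality. The augmentation exists because pure greedy demonstrably
loses 1–2% of matchable pairs on dense instances, which would
understate both precision and recall for no principled reason; with it,
the matching size always equals the maximum matching (verified against
networkx). Precision, recall and F1 follow the usual definitions with
zero denominators mapped to 0.

## GE-like classification and interaction range

An SV sequence longer than 200 bp that aligns to a bacterial genome
with > 80% identity over > 80% of its own length is classified
*GE-like* (genetic-exchange-like); sequences ≤ 200 bp are out of scope
(`too_short`), and the rest are `noGE-like`. Coverage is computed on
the SV sequence length, not the subject span. The best hit maximises
identity × coverage. Hits into predicted prophage regions at > 80%
identity and > 50% coverage set a separate flag so phage-on-phage
homology inside bacterial assemblies is not misread as exchange. The
interaction range of a GE-like SV is the taxonomic rank of the last
common ancestor of all matched bacterial genomes (species … domain,
with a `none` sentinel when even the domain differs; a single genome
reports its deepest annotated rank).

## HT index (codon-neighbour typicality)

The HT index scores how typical a gene's codon-pair usage is for its
genome. A first-order Markov chain over the 64 codons is trained on
all genes of the genome: adjacent in-frame codon-pair counts are pooled,
Laplace-smoothed (pseudocount 1) and row-normalised. A gene of codons
`c_1 … c_L` scores

    HT = (1/(L-1)) * sum_i log2 P(c_{i+1} | c_i),

the mean per-transition log-probability in bits. Under a uniform model
every gene scores exactly −6 (= log2(1/64)), a useful calibration
point. Genes acquired from a compositionally different donor score
lower than native genes; with transition matrices at mean row
total-variation ≥ 0.3 and 300-codon genes, native and foreign genes
separate with Mann-Whitney p ≪ 0.01. Training includes the scored gene
itself (leave-one-out would change scores by O(1/n) here and is
omitted).

## HGT directionality from tree topology

On a rooted gene tree whose leaves are kingdom-labelled (bacterial /
viral, parsed from `B_`/`V_` name prefixes), a transfer is called for
every maximal one-kingdom clade C whose surrounding context is purely
the other kingdom: the sibling leaves (under the other children of C's
parent, required non-empty) and the aunt leaves (under the other
children of C's grandparent) must all be the opposite kingdom. Viral
recipients nested in bacterial context give a bacteria-to-phage (B_to_P)
event and vice versa. A clade hanging directly off the root is never an
event — with no grandparent there is no second level of context, and a
clean two-kingdom bipartition would otherwise read as two reciprocal
transfers. Requiring purity of both sibling and aunt sets is the
conservative reading of "nested"; events are counted per maximal clade,
not per leaf. An optional support threshold filters events whose
parent node's support value is too low (default 0 = off).

## CRISPR-spacer host prediction

A spacer links a phage to the spacer's source taxon when some genome
window of spacer length, on either strand, is within 2 substitutions
(Hamming distance; no indels). `N` mismatches everything on either
side. Full-length matching with ≤ 2 substitutions automatically
enforces > 95% identity for spacers ≥ 41 bp; shorter spacers carry
their mismatch count so a stricter caller can refilter. The scan is a
vectorised sliding-window comparison verified base-for-base against a
pure-python oracle. This substitution-only rule replaces a
short-read-blast + bit-score recipe with a single auditable criterion;
gapped near-matches are deliberately not found.

## Cohort statistics

* SV density: SV count × 10⁶ / genome length (SVs per Mb).
* Gene–SV overlap: a gene is in an SV region iff its half-open interval
  intersects a DEL/DUP/INV interval by ≥ 1 bp or contains an INS
  breakpoint (property-tested against a per-base oracle).
* Functional enrichment: per level-2 category, a one-sided
  hypergeometric (Fisher) test for over-representation among SV-region
  genes versus conserved-region genes, Benjamini-Hochberg adjusted
  within the run; the background is all genes of the genomes analysed.
* Lifestyle comparison: two-sided Mann-Whitney U between temperate and
  virulent SV densities — exact null for tie-free samples of combined
  n ≤ 20, normal approximation with tie correction otherwise, p = 1
  for fully tied input.
* Sharing network: edge (phage, bacterial genus) weighted by the number
  of the phage's GE-like SVs with a qualifying hit to any genome of the
  genus; genomes lacking a genus fall back to their deepest annotated
  rank with a warning. Per-edge abundance correlation is the Pearson r
  of the two abundance rows across samples (undefined for zero-variance
  rows, reported missing), plus one summary correlation between edge
  weight and pair correlation.

## The synthetic cohort

The generator emulates the *structure* of a virome-enriched long-read
cohort at the callset level; it does not simulate reads, sequencing
error, or assembly. Defaults (the conditions under which the test
suite scores the pipeline):

* 50 phage genomes of 15–25 kb at GC 0.45, plus 10 unrelated decoy
  genomes the prefilter must reject, and 10 bacterial genomes of
  40–60 kb. (Genome sizes are at the small end of gut-phage reality to
  keep the default run fast; all sizes are config fields.)
* 400 truth SVs (120 INS, 120 DEL, 80 DUP, 80 INV) of 100–1000 bp,
  implanted ≥ 100 bp from genome ends and ≥ 150 bp apart, so truth
  intervals never overlap. Length bookkeeping is asserted exactly:
  INS/DUP add their length, DEL subtracts, INV preserves.
* 5 samples × 4 simulated callers. Each caller misses a truth SV with
  probability ~0.1, jitters starts by Normal(0, 5–10 bp) and lengths by
  ~2%, draws read support as 1 + Poisson(9), and adds ~2 false
  positives per genome. False positives are *caller-private by
  construction*: a placement that would reciprocally overlap (≥ 0.8)
  another caller's false positive of the same type is redrawn. This
  models the premise that caller artifacts arise from each caller's own
  heuristics — and it is what makes "no false positive survives the
  ≥ 2-caller filter" a meaningful guarantee. Without it, uniform
  placement produces a handful of chance cross-caller coincidences per
  cohort which no consensus method could reject even in principle.
* 40 bacteria→phage transfer events of 300–1500 bp at 5% substitution;
  the generator emits the ground-truth-exact hit table (realized
  identity, full coverage) in place of an external aligner, plus random
  decoy SV sequences with no hits and a few ≤ 200 bp entries to
  exercise the length gate. Two events receive synthetic prophage
  hits.
* Codon genes: 50 native + 50 foreign genes of 300 codons from two
  Dirichlet-drawn transition matrices at total variation ≥ 0.3;
  in-frame stops are resampled away during generation.
* Trees: planted events are built as `((recipients, x), y)` subunits —
  recipient clade of 1–2 opposite-kingdom leaves with donor-kingdom
  sibling `x` and aunt `y` — joined randomly with the remaining donor
  leaves, which guarantees each planted event satisfies the nesting
  definition and creates no spurious ones.
* Spacers: 30 true spacers (32 bp, up to 2 planted substitutions) plus
  decoys verified by brute force to have no ≤ 2-mismatch window in any
  phage.
* Abundance: lognormal(μ = 0, σ = 0.5) across 91 samples. Each
  (phage, donor genus) pair from the transfer events shares a latent
  Gaussian at ρ = 0.8; the genus owns the latent so one genus can
  couple several phages. σ = 0.5 keeps the lognormal attenuation of
  the latent correlation small (Pearson ≈ 0.78 for ρ = 0.8); a phage
  receiving from several genera only tracks its first, so cohort-level
  mean edge correlation sits below the per-pair value — as it would in
  real data, where a phage's abundance follows its primary host.
* Lifestyles: half the phages are temperate and receive twice the SV
  assignment weight, planting the density contrast the lifestyle
  comparison should recover; one functional category
  (`integration:recombinase`) is drawn 6× more often for genes
  overlapping truth SVs, planting the enrichment signal.

What passing on this cohort does **not** show: robustness to read-level
artifacts, assembly fragmentation, alignment ambiguity between related
genomes in the catalogue, caller biases correlated across callers, or
gapped homology — none of which the generator models.

## Problem sizes and determinism

The default test-suite problem sizes (50 genomes × 5 samples, 400 SVs,
100 trees, 1000 spacer fixtures) run the whole suite in well under a
minute of compute; they were chosen as the smallest sizes at which the
statistical assertions have comfortable margins. Every generator is a
pure function of its seed (identical seeds give byte-identical files);
the orchestration derives per-stage child seeds from one master seed.

## Known limitations

* CAST with binary edges and `t = 0.5` can split long overlap chains of
  short SVs into multiple clusters; downstream this surfaces as a
  duplicate nonredundant SV rather than a miss.
* INS comparisons use position and length only; inserted-sequence
  similarity is not consulted during merging.
* The HT index is a relative score: it orders genes within a genome but
  is not comparable across genomes with very different codon entropy.
* The nested-clade rule cannot see transfers whose context was pruned
  from the gene tree, and reports clades, not individual genes.
* Spacer matching finds no gapped matches by design.
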