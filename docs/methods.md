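# Methods

## Model and assumptions

The caller targets **isolated SNPs only**: substitutions whose nearest
other variant is more than *k* bases away. Under that assumption the
de Bruijn graph of the pooled samples contains, per SNP, exactly two
parallel paths of *k* internal vertices (the k-mers covering the variant
base in each allele) between a shared branching vertex and a shared merge
vertex, and the two assembled branch strings have length 2k+1 with a single
mismatch at the middle position. Indels, clustered SNPs and structural
variants violate the equal-length / degree-clean structure and are out of
scope by design.

The graph carries **both strands as distinct vertices** (each surviving
(k+1)-mer adds its own edge and its reverse complement's). Consequently
every bubble is discovered twice, once per orientation; the reported set is
deduplicated by mapping each unordered sequence pair to the lexicographic
minimum of itself and its reverse-complement mirror. Edges are
deduplicated (topology only): multiplicity and per-edge coverage are not
stored because detection uses degrees and adjacency alone.

## Superstep schedule

Messages seeded at every vertex with outDegree > 1 are forwarded for
**k+1 supersteps**, with the degree gate (inDegree = outDegree = 1 at the
receiving vertex) active on supersteps 1..k and inactive on the final
superstep, where the merge vertex — whose degrees are unconstrained — may
receive. This is the only schedule consistent with k internal vertices and
k+1 edges per branch. A message is dropped when its destination already
appears on its path, which bounds path growth on repeats and cycles.
Inboxes are processed in sorted vertex order and results are
canonically sorted, so the output is a pure function of the graph:
partition counts and assignments cannot affect it (tested).

### Degree-gate consequence at tiny k

When k is very small, the reverse strand of one branch can share vertices
with the forward strand of the other branch (for example when the two
alleles are complementary bases and a flank k-mer happens to recur). The
affected internal vertices then have degree 2 and the gate rejects the
bubble — matching the structural definition, which requires clean internal
vertices. This is a property of the method, not an implementation choice;
at realistic k (≥ 15 on non-repetitive sequence) such collisions require a
2k-base coincidence and do not occur in practice.

## Parameters

| parameter | default | meaning / guidance |
|---|---|---|
| k | 21 | k-mer size (bases); ≤ 31 so a (k+1)-mer fits one 64-bit word. Larger k separates repeats but thins coverage per window. |
| τ | 5 | minimum (k+1)-mer coverage per sample; windows below τ are treated as sequencing errors. Raise with coverage; past the mean window coverage recall collapses. |
| c | none (CLI requires it) | greedy stop threshold for read clustering, in [0,1]. 0.3 is a reasonable heuristic starting point: high c → many small clusters; low c → few clusters that may mix regions. Not a calibrated value. |
| B | 4 × computing units | number of LPT bins, following the benchmarked deployment ratio. |
| cluster k | graph k | k-mer size used for Jaccard similarity; independent of the graph k. |

## Clustering and binning details

Cluster–cluster similarity is the Jaccard index between the two clusters'
**representatives** (the member read maximising mean similarity to its
co-members; ties go to the lower read id). Merging is greedy best-first
with deterministic tie-breaks (smallest (min member id, max member id)
pair) and stops when the best similarity is strictly below *c*, so c = 0
yields one cluster and c > 1 yields singletons. Cluster weights for LPT
are the number of (k+1)-mers in the member reads, at the graph's k. LPT
sorts jobs by non-increasing weight (lower job id first) and assigns each
to the least-loaded bin (lower bin id first); it is the classical
(4/3 − 1/(3B))-approximation for P||C_max, verified against an exhaustive
optimum on small instances. A vertex observed in reads of several clusters
follows the cluster with the most occurrences of its k-mer (ties: lowest
bin id); a backward-strand vertex observed in no read inherits its reverse
complement's bin.

## Synthetic data: what it emulates, what it does not

The generator emulates a two-individual sequencing experiment: sample A is
drawn from a uniform random genome, sample B from a copy carrying *n*
planted substitutions with pairwise distance > k; reads of fixed length are
sampled uniformly from either strand with i.i.d. substitution errors.
Stages draw from independent child seeds of one master seed, so outputs are
bit-reproducible and independently variable.

Deliberate simplifications: a uniform i.i.d. genome (no repeats, no GC
bias — real genomes produce ambiguous k-mers and extra branching that this
fixture cannot exhibit), substitution-only errors (no indels, no quality
profiles), haploid samples (no heterozygosity), and uniform coverage. A
green end-to-end test therefore establishes the correctness of the
*machinery* — counting, graph construction, detection, scoring — at stated
coverage and error rates, not calling accuracy on real genomes.

SNPs are planted at least `margin` bases from the genome ends
(default: k, the minimum for a full 2k+1 context). The end-to-end fixtures
use `margin = read_len` because uniform read starts give linearly decaying
coverage within a read length of the ends, where windows would be filtered
at any realistic τ.

## Partitioning benchmark fixture

The benchmark needs regions that clustering *can* isolate, so it generates
60 independent random regions (no shared k-mers between regions), one
centred SNP each, with error-free 100 bp reads at 10×. The region length,
160 bp, makes all same-strand reads of a region mutually overlapping, so a
region collapses to one or two clusters rather than a left/right chain;
with longer regions the dendrogram fragments and bubbles straddle bins,
which is a genuine property of the strategy (the stop threshold trades
cluster purity against region coverage), not of the implementation.
Hash partitioning at the same partition count (8) scatters the 2k+2 = 32
vertices of each bubble almost uniformly (mean span ≈ 7.9); the
cluster-driven strategy keeps 80–90% of bubbles in a single bin across
seeds.

## Numerical and edge-case choices

- Counting is vectorised: reads are joined with a sentinel byte, windows
  accumulate via shifts over a uint64 array, and windows touching a
  non-ACGT character are masked out; `np.unique` produces the tally.
  Lower-case (soft-masked) bases are accepted and upper-cased.
- τ is applied per sample before merging; merged frequencies are sums over
  the samples where the window survived.
- Precision over an empty call set is 0 by convention; each truth SNP is
  matched at most once, strand-insensitively.
- The stable vertex hash is the splitmix64 finaliser, independent of
  `PYTHONHASHSEED`.
- Multi-allelic sites report every unordered pair of vertex-disjoint
  equal-length branches; within a pair the sequences are ordered
  lexicographically.
- Worker/thread counts (CLI `--threads`) never influence output bytes.

## Known limitations

- Hierarchical clustering is O(N²) in the number of reads (pairwise
  similarities plus a lazy merge heap); it is a diagnostic for modest read
  sets, not a scalable partitioner.
- No genotyping or statistical confidence model: a bubble is a call.
- No VCF output — without a reference there are no coordinates to place
  calls on; bubbles are reported as sequence pairs.
- Calling degrades on repetitive sequence exactly as the graph structure
  dictates: repeats create extra branches that either block the degree
  gate (missed SNPs) or, if they mimic a clean bubble, produce false
  pairs.
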