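# Methods

This note documents the models implemented in `barcodelim`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmark does and does not establish about real data.

## Data model and QC

A library is an ordered set of aligned COI barcode records (equal-length
aligned sequences over the IUPAC alphabet plus gaps). Alignment itself is
out of scope: the COI barcode is a fixed-coordinate 651-bp amplicon and
inputs are expected pre-aligned.

*Length filter.* Length is counted over non-gap characters; the default
minimum of 400 bp is deliberately below the ~459 bp floor observed in
real barcode libraries, so it removes only fragments too short to be
informative, never a plausible barcode.

*Stop-codon screen.* The ungapped sequence is read in all three forward
frames against the vertebrate mitochondrial code (stops TAA, TAG, AGA,
AGG, taken from Biopython's table 2); a record passes if at least one
frame is open. Because the fragment sits mid-gene, every complete codon is
treated as internal; codons containing ambiguity codes never count as
stops (the screen is a red flag for pseudogenes, so uncertainty is
resolved leniently). Sequences shorter than one codon are flagged with a
distinct reason.

*Haplotype pruning.* Identity is exact string equality on the aligned
sequence, gaps and ambiguities included. This is deterministic and
conservative: two sequences differing only by an N are kept separate
rather than guessed identical. The representative is the first record in
input order; the mapping back to members is a partition of all input ids
and is used to propagate OTU labels after delimitation.

## K2P distances

Distances use the Kimura two-parameter correction
`d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)` with P and Q the transition and
transversion proportions over sites where *both* sequences carry an
unambiguous base (pairwise deletion). Pairwise deletion is essential when
sequences of unequal length (459–651 bp) are pooled; complete deletion
would discard most of the alignment. IUPAC ambiguity codes other than the
four bases are treated as missing rather than probabilistically resolved.
Pairs with no comparable sites, or where a log argument is non-positive
(saturation), are undefined and reported as NaN; group statistics exclude
them with a warning instead of clamping to an arbitrary ceiling.
User-facing tables report distances ×100 (percent); the internal unit is
always substitutions/site.

Per-group statistics follow the standard barcoding-gap pair: the maximum
intraspecific distance (NA exactly for singletons) and the
nearest-neighbor distance (minimum distance from any member to any
non-member, with the neighbor's label retained).

## Trees

*Neighbor joining* implements the Saitou–Nei recurrences
(Q(i,j) = (N−2)d(i,j) − R_i − R_j, branch lengths
v_i = d/2 + (R_i−R_j)/(2(N−2)), reduction
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2) with a fixed tie rule — the lowest
(row, column) pair in current matrix order — so runs are bit-for-bit
reproducible. Negative branch estimates are clamped to zero with the
deficit moved to the sibling branch (standard practice) and logged. On
exactly additive matrices NJ provably recovers the generating tree; the
test suite checks this on random trees and cross-checks the topology
against scikit-bio's implementation.

*UPGMA* (size-weighted average linkage, node height = merge distance / 2)
is delegated to scipy's hierarchical clustering and serves as the built-in
ultrametric stand-in for an externally inferred Bayesian chronogram —
a documented simplification; externally built chronograms can be imported
as newick instead. Average linkage is monotone, so heights never invert.

*Rooting* places the root at the midpoint of the edge separating a
monophyletic outgroup; a non-monophyletic outgroup is an error that lists
the intruding tips. *Clock scaling* divides heights by a strict-clock
rate; the default calibration is 0.012 substitutions/site/My (1.2% of
genetic distance per million years, the usual COI fish calibration), so a
height of 0.012 reads as 1 My.

## Distance-based delimitation

*RESL-like single linkage.* BOLD's Refined Single Linkage and its BIN
registry are proprietary beyond the published outline, so the package
implements the documented single-linkage core — OTUs are connected
components of the graph with edges where d < threshold — at BOLD's seed
threshold of 0.022 substitutions/site, and labels results "RESL-like",
never BINs. OTU labels are the lexicographically smallest member id,
making partitions order-independent up to relabelling.

*ABGD-style gap partitioning.* For each prior ceiling P on intraspecific
divergence (geometric series, defaults p_min=0.001, p_max=0.1, 10 steps —
the original tool's published defaults), the sorted pairwise distances
are scanned above P for the first successive gap wider than X=1.5 times
the mean successive gap among the smaller distances; the matrix is split
by single linkage below the gap midpoint and the rule recurses within
each group until no gap is found. One partition per prior is returned; a
modal rule (most frequent OTU count, ties to the fewer-OTU side) picks
the headline partition, since real analyses report a single count without
stating the prior.

## Tree-based delimitation

*PTP / mPTP.* Branch lengths (substitutions/site) are modelled as
exponential draws from two classes. A delimitation is an anti-chain of
species-root nodes covering all tips; edges strictly inside a species
subtree are coalescent-class, all others speciation-class. With n edges
of total length S a class contributes the profile term n·ln(n/S) − n; in
multi-rate mode (mPTP) every species has its own coalescent rate. Edges
shorter than min_br (default 1e-4, roughly one substitution across a
barcode) are excluded. The search combines (i) hill climbing over
split/merge moves with first-improvement in deterministic node order,
from the one-species and all-tips starts plus seeded random restarts,
(ii) threshold starts — species as maximal subtrees free of long edges,
for a sweep of length cuts — and (iii) a coordinate-ascent polish that
alternates an exact dynamic program over delimitations (optimal for fixed
rates, since the objective then decomposes over subtrees) with ML rate
updates, seeded from a fine geometric rate grid. The optimum is always a
fixed point of that DP at its own implied rates, which is why the grid
step (8%) is chosen finer than the empirically measured width of optimum
basins; on 8–12-tip trees the search matches exhaustive enumeration over
all delimitations in every tested instance.

*GMYC / mGMYC.* On an ultrametric chronogram, nodes older than a
threshold T are Yule speciation events (per-lineage rate λ_yule), younger
nodes are within-cluster coalescences (rate λ_coal·m(m−1) for a cluster
with m lineages); scaling exponents are fixed at 1, removing two weakly
identified parameters. The likelihood is the waiting-rate form: each
inter-event interval of duration x contributes ln(b) − b·x with total
rate b = λ_yule·k + λ_coal·Σ_j m_j(m_j−1), where k counts species-level
lineages (cluster stems included down to each cluster's MRCA) and the
root event is conditioned on. An alternative "labelled-density"
formulation (event factors equal to per-lineage/per-pair rates only) was
evaluated and rejected: it loses the lineage-count signal that
distinguishes coalescent bunching from Yule spread and badly over- or
under-splits; the waiting-rate form recovers simulated cluster counts.
T is profiled over internal node heights, with the two rates maximised
per threshold by L-BFGS-B on analytic gradients (closed forms when one
class is empty). The null — one cluster, pure coalescent — is the
T ≥ root-height boundary of the same likelihood, so LR = 2(logL−logL₀) is
non-negative by construction; the p-value uses a chi-square with df=2
(contested in the literature and therefore configurable). mGMYC greedily
gives single clusters their own, younger thresholds, accepting a split
when AIC improves (one extra threshold parameter per split); it is a
stand-in for the published multi-threshold heuristic, as is the greedy
mPTP refinement.

By default PTP runs on the NJ substitution tree and GMYC on the
UPGMA/imported chronogram, mirroring the usual ML-tree/chronogram split.

## Consensus and gap analytics

The "50% consensus" across methods is implemented as a pairwise quorum
graph: co_assignment(i,j) is the fraction of input partitions placing i
and j in one OTU, and consensus OTUs are connected components of the
graph with edges where that fraction reaches the quorum (default 0.5).
The aggregation rule is this package's explicit interpretation —
published studies rarely define theirs — and components held together
only by transitive chains (every edge at quorum, some internal pair
below) are logged so the choice is auditable.

The fold-ratio between nearest-neighbor and maximum-intraspecific
distances is reported under both readings of "X-fold higher on average":
the ratio of means (headline) and the mean of per-group ratios, because
the phrase is ambiguous. Singleton groups contribute to the
nearest-neighbor mean but are excluded from the max-intra mean; groups
with zero max-intra are excluded from the per-group-ratio mean.
Histograms use 1% bins. The per-species report lists only species split
into more than one consensus OTU, with OTU sub-rows and NA for singleton
OTUs' max-intra cells.

## Synthetic benchmark

The generator emulates the statistical structure the analyses assume: a
Yule species tree (dendropy), a multispecies-coalescent genealogy within
it (msprime, one haploid population per species tree branch, splits at
the species divergence times), and K2P sequence evolution (kappa = 4,
typical for COI) along the gene tree at 651 bp. Times are simulated in My
and converted to substitutions/site by the 0.012/My clock. Defaults: 10
species × 10 samples; expected within-species TMRCA 0.002
substitutions/site, which yields typical maximum intraspecific K2P
distances of 0.5–1% after pairwise-path doubling and 651-bp estimation
noise; a floor of 0.02 substitutions/site on species split depths plus a
Yule rate of 0.46/My put interspecific divergences at roughly 4–15%. The
floor is the "controlled divergence" knob: it keeps the coalescent depth
an order of magnitude below the shallowest split, the regime in which a
barcoding gap exists by construction. Two simulator details matter for
correctness: the Yule simulator stops at the n-th birth (leaving the
youngest split at age zero), so terminal branches are extended by an
Exp(n·λ) draw — the memoryless continuation of the pure-birth process to
a random inspection time; and the root sequence is uniform over the four
bases unless ORF-preserving mode is on, in which case substitutions
creating frame-1 stop codons are rejected so the stop-codon screen is
exercised meaningfully (off by default, since the K2P machinery does not
need it).

What passing tests on this benchmark show: the estimators and searches
are correct and the pipeline recovers a clean, well-separated species
inventory with high probability, and does not invent structure in
single-population null data (GMYC rejection rate ≤ 20% at α = 0.05,
tolerating the method's known anticonservatism). What they do not show:
robustness to alignment error, indels, heterogeneous sampling across
species, rate variation among lineages or sites, introgression or gene
flow — real libraries contain all of these, and deep within-species
coalescences (which the simulator does produce in its tails) already read
as "cryptic diversity" exactly as in empirical studies.

## Numerical and reproducibility choices

All randomised components (simulator, PTP restarts) take explicit integer
seeds and use integer-seeded generators only; reruns are byte-identical,
and the pipeline summary is written with sorted keys so equality can be
checked on the file. Tie-breaks are deterministic everywhere (lowest
index pair in NJ, first-improvement in deterministic node order in the
searches, lexicographically smallest member id as OTU label).
Ultrametricity is enforced at 1e-9 on root-to-tip spread (relative for
GMYC inputs). Problem sizes in the test and acceptance runs — 50-replicate
recovery and null studies at 100 records each, 20-tree search-oracle
comparisons at 8–12 tips — were chosen to keep each suite fast while
leaving the binomial pass criteria (e.g. ≥ 90% of 50) statistically
meaningful.

## Known limitations

- RESL's refinement stage and BIN identifiers are not reproducible from
  public information; the single-linkage stand-in is clearly labelled.
- The multi-rate variants (mPTP, mGMYC) are greedy AIC-guided
  refinements, not exhaustive multi-threshold searches.
- UPGMA is a crude chronogram; for publication-grade GMYC input an
  external Bayesian chronogram should be imported.
- The GMYC p-value inherits the df=2 convention; its null calibration is
  approximate and anticonservative, as widely reported.
- No alignment, no rate-variation correction, and no model-based
  distances beyond K2P.
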