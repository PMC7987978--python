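# Methods

This note documents the models, parameter choices and numerical
conventions behind `hicphaser`, and what the synthetic benchmark does and
does not establish about real data.

## LOH detection

Each chromosome is cut into fixed windows of `window_bp` (default
1,000,000 bp). For a window holding `N` SNP sites of which `k` are called
heterozygous on the cancer genome, and a reference heterozygous proportion
`p` for the same window on a normal genome, the heterozygous count is
modelled as `X ~ Binomial(N, p)` and the window is called LOH when the
exact, inclusive lower-tail probability `P(X ≤ k)` falls below `alpha`
(default 0.05, no multiple-testing correction — the procedure is used as a
per-window screen). The tail is evaluated through the regularized
incomplete beta function, which agrees with direct pmf summation to
≤ 1e-12 over the tested range (the brute-force summation is kept as the
test oracle). Degenerate reference proportions (0 or 1) are rejected.

Windows with fewer than `min_snps` sites (default 10) cannot be tested;
they inherit the label of the nearest tested window, with ties resolved to
LOH so that sparse chromosome ends — a hallmark of true LOH, which removes
het SNPs — are not spuriously called diploid. Maximal runs of LOH windows
merge into regions (0-based half-open bp intervals, window-aligned by
construction); SNPs inside them are removed before phasing, and the
remaining SNPs split into continuous non-LOH stretches that are phased
independently.

The normal profile is a TSV of per-window proportions (emulating a
GM12878-style reference); a single genome-wide fallback proportion is
accepted for synthetic runs. The choice of SNP universe for the
denominator is deliberately left to the profile's producer.

## Built-in phaser

The external HAPCUT2 adapter is strictly pluggable: downstream code sees
only `HaplotypeBlock` (strictly increasing SNP indices, per-SNP h1 allele).
The built-in fallback phaser makes the pipeline self-contained: every SNP
pair co-observed by a fragment votes cis (equal alleles) or trans; pairs
whose majority margin reaches `min_support` (default 2) become edges
weighted by that margin; each connected component is phased along its
maximum-weight spanning tree. Tied votes drop the edge, leaving the SNP
for gap filling. Singletons become one-SNP blocks, which are emitted
unphased: a lone heterozygous SNP carries no phase information.

With the synthetic generator's default coverage, adjacent SNPs share
10–20 informative pairs, so a 1% per-call error rate leaves the majority
vote essentially error-free; this is why end-to-end AER stays ≪ 1% and is
not evidence about low-coverage libraries.

## Switch-error correction

Allelic copy-number imbalance makes one haplotype's coverage dominate. At
every inter-SNP position `i` (between SNP `i-1` and SNP `i`) four counts
are maintained by forward/backward recurrences: `c1_before[i]` = positions
`< i` with `cov1 > cov2`, `c1_after[i]` = positions `≥ i` with the same,
and the two `c2` analogues for `cov1 < cov2`; ties count in neither.
`r_before = c1_before/c2_before` and `r_after = c1_after/c2_after`; a
position qualifies as a switch candidate when one ratio exceeds
`switch_hi` (default 2) and the other falls below `switch_lo` (default
0.5). Among qualifiers the ratio-of-ratios `min(r)/max(r)` is minimised;
the phase after the chosen position is flipped (and the coverage columns
swapped) and the scan repeats until no candidate remains, capped at one
iteration per block SNP to guard against oscillation.

Numerical conventions: a zero denominator yields `+inf`; a position with
both ratios infinite never qualifies; `min/inf` counts as 0 when the
minimum is finite. Because a zero count collapses the ratio-of-ratios to 0
for many positions at once, equal values are tie-broken by the largest
total dominance support `max(c1,c2)_before + max(c1,c2)_after`, which
uniquely selects the true boundary on clean data (without this the
selected position can drift far from the switch); any remaining tie keeps
the leftmost position. A limitation inherent to the ratio criterion: a
switch is only visible when the segments flanking it are clearly
unbalanced in opposite directions — two switches delimiting a short
inverted segment between two long same-direction segments of similar size
can escape detection.

## Coverage matching graph and Minimum Multiple s-t Cut

Each SNP contributes two vertices (side *a* = the allele its block assigns
to h1, side *b* = the complement; for singletons *a* = alt). A cross-block
SNP pair (s_i, s_j) receives a 4-edge bundle when (1) their distance is at
most `max_dist` (1 Mbp), (2) each is among the other's `n_nearest` (5)
closest cross-block SNPs, (3) at least one belongs to a block of
`min_block` (100) or more SNPs, and (4) all four side coverages exceed
`min_cov` (10). Natural logarithms are used throughout.

Two weight modes are provided:

* **as-printed** — per-edge reciprocals of the coverage-normalised
  log-likelihood terms, `w_i(x,y) = −1/[p(s_j^y)·log p_i^x]`, summed over
  both directions and normalised so the four weights sum to 1.
* **matched-support** (default) — a pair-level posterior from the same
  binomial model: `W(aa|bb) = 1/(1+exp(L(ab|ba) − L(aa|bb)))` with
  coverage-normalised joint log-likelihoods, split equally over each
  hypothesis's two edges. This mode exists because the reciprocal
  transform can put the larger weight sum on the coverage-*mismatched*
  orientation (e.g. both SNPs at proportion 0.75 give sums 0.336/0.664),
  inverting the intended meaning of the cut.

A bundle survives only if the smaller of the two orientation sums divided
by the larger is at most `reliability_thresh` (0.4). Note the interaction
with coverage normalisation: because likelihoods are computed on
proportions, the per-pair evidence does not sharpen with depth, and a
coverage-matched pair at exactly 2:1 imbalance has posterior ≈ 0.614 —
ratio 0.63 — and is filtered in *both* modes. Under the published
thresholds, block assembly therefore engages from roughly 3:1 imbalance
upward (where the matched posterior is 0.75, ratio 1/3); in 2:1 regions
the pipeline relies on the phaser producing long blocks directly, and on
LD gap filling for the remainder. The tests document this boundary
explicitly.

Adjacent SNPs inside one block are chained by infinite-weight a–a / b–b
edges, so no feasible cut can break a block's internal phasing.

Partitioning the CMG into two sides with exactly one vertex of each pair
per side, minimising the cut weight, is the Minimum Multiple s-t Cut
problem; it is NP-hard by reduction from Max-Cut (each source vertex
becomes a pair; each source edge (i, j), i < j, becomes the single edge
(i^a, j^b); the reduced optimum equals total weight minus the max cut —
shipped as an executable test utility). The solver is a revised Karger
heuristic: an association graph has one vertex per SNP pair and, for every
bundle, an edge weighted `1/(−r₁·log r₁ − r₂·log r₂)` where r₁ is the
proportion of bundle weight supporting the aligned orientation (missing
edges count 0; r₁ clamped to [1e−12, 1−1e−12]). Each of `M` runs (default
100) draws a weighted random permutation of association edges (exponential
races, equivalent to sequential sampling without replacement proportional
to weight) and contracts them in order with a parity union-find: a
contraction merges two pair-groups in the orientation with the larger
current inter-group supporting weight (ties random), skipping edges whose
endpoints were already merged; infinite edges pre-merge their groups. The
best of the `M` resulting cuts is returned; runtime is linear in
(|E|+|V|)·M. A brute-force enumerator (≤ 15 pair-groups,
lexicographic tie-break) serves as the exactness oracle in tests.

## Gap filling and completion

Tiny blocks left in coverage-balanced regions are clustered to the nearest
main block (≥ `min_block` SNPs) of their stretch by minimum pairwise SNP
distance (ties to the leftmost centre) and passed, with the main haplotype
as a phased seed, to a statistical phasing engine through an adapter. The
engine's LD model is outside this package; a Beagle shell-out adapter and
a mock engine (used in tests) implement the boundary. Engine output is
re-oriented so every seed SNP keeps its input phase; missing sites stay
unphased; without an engine the cluster is skipped with a warning and the
pipeline still completes.

Completion builds a support graph per chromosome: one vertex per LOH
region, two per non-LOH region (its haplotypes), and an edge (L, h)
weighted by the number of read pairs with one mate inside L and the other
making calls matching haplotype h (majority over the mate's matching
calls; exact ties vote for neither). All side assignments — one
orientation bit per region with the first pinned to break the global flip
symmetry, one side bit per LOH vertex — are enumerated and the assignment
with minimum removed (cross-side) weight wins, ties resolving to the
lexicographically smallest vector. Past 2^19 assignments the solver falls
back to the contraction heuristic on an equivalent pairing (each LOH
vertex paired with an isolated dummy). Chromosomes without LOH regions
keep their non-LOH regions mutually unoriented and are emitted as separate
phase sets — completion is only defined where LOH regions intervene.

## Evaluation

AER of a block against truth over their SNP intersection:
`min(count°, countʳ)/(count° + countʳ)`, where count° counts identical
ordered allele pairs and countʳ reversed ones; flip-invariant, reported as
NA on an empty intersection. Completeness = number of blocks with ≥ 100
SNPs in non-LOH regions and the percentage of phasable (heterozygous,
germline, non-LOH) SNPs they contain. LOH accuracy = interval-arithmetic
precision (overlap/called length) and sensitivity (overlap/truth length).

## Synthetic data

The generator plants: Poisson-spaced SNPs (mean gap 2 kb — ~10,000 SNPs on
the default 20 Mb chromosome); germline heterozygosity 0.6; a 3% somatic
fraction excluded from the known-site list; two window-aligned LOH
intervals (~25–40% and ~70–80% of the chromosome) in which heterozygous
sites survive at rate 0.08, the lost allele collapsing onto the surviving
haplotype (drawn per interval); and a 2:1 allelic copy ratio elsewhere.
The normal profile is the per-window germline heterozygous proportion of
the same simulated genome (Laplace-smoothed), playing the role of the
matched normal cell line.

Hi-C pairs are simulated at SNP resolution: the first read anchors on a
uniformly chosen SNP, the second end sits at a distance drawn from a
truncated `d^{-1}` contact-decay law (minimum 1 kb) snapped to the nearest
SNP, the haplotype of origin is drawn proportionally to the local copy
numbers (pairs whose haplotype is absent at either end — LOH deletions —
are redrawn), and every SNP within the 150 bp read span of each end
reports the haplotype allele, flipped with probability ε (default 0.01).
`n_pairs` therefore counts SNP-informative pairs; at the default scale
this yields ≈ 100 calls per SNP. Each fragment records its mates' leftmost
positions for the completion step, and the pairs can be emitted as a text
SAM against a synthetic all-'A' reference for exercising the alignment
reader.

What the benchmark does **not** model: restriction-site, GC and
mappability bias, chimeric/trans ligation noise, subclonal LOH, indels,
and the fact that real informative pair yield per sequenced read is far
lower. Passing tests therefore demonstrate the correctness of the
algorithms under their stated model, not sequencing-depth requirements of
real libraries.

## Problem sizes and determinism

The acceptance run uses a 20 Mb chromosome (~10,000 SNPs, 500,000
informative pairs) — large enough that every stage (windowed test,
spanning-tree phasing, switch scan, CMG, completion) operates in its
intended regime while the whole recomputation stays fast on one CPU.
Solver and simulation randomness flow from a single integer seed through
`numpy.random.default_rng`; identical (instance, M, seed) triples
reproduce identical cuts, and identical pipeline configs reproduce
byte-identical outputs.
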