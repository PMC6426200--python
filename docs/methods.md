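# Methods

This note documents the statistical models implemented in `mitopop`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that make results reproducible.

## Coordinates, variants and motifs

All coordinates are 1-based inclusive, as is universal for human mtDNA;
variants are reported relative to a reference segment in standard motif
notation: `16223T` (substitution), `309.1C` (first inserted base after
position 309; `309iC` is accepted on input), `16166d` (deletion), `@16189`
(back mutation). Strand is not modelled: sequences are taken as given, with
reverse-complemented input detected at alignment time by comparing the
identity of both orientations. The default analysis window is HVRI,
positions 16,000–16,400.

Indels anchored at positions 309, 522, 573 and 16193 and substitutions at
16519 are excluded from all phylogenetic computations (haplogrouping,
networks, dating). These are classic length-heteroplasmic homopolymer
tracts and a mutational hotspot whose recurrence carries no phylogenetic
signal. Excluded calls are returned alongside the motif, never silently
dropped. "Around" is implemented as a ±5 window on the indel's anchor
position: aligners may legally place a homopolymer-run indel at any
position of the run (an insertion in the 16184–16193 C-tract can surface
anchored at 16191), so exact-position matching would leak excluded events
back in.

## Alignment and variant calling

Query sequences are aligned globally with free end gaps (Biopython
`PairwiseAligner`; match +1, mismatch −1, gap open −2, gap extend −1).
HVRI fragments of one haplotype differ by a handful of substitutions, so
the scoring hardly matters; it is pinned for determinism. Alignments below
80% identity are rejected as non-homologous, and query end-gap regions
(missing fragment coverage) produce no calls — a partial fragment is not a
stack of deletions. Sequences shorter than half or longer than twice the
window are rejected before alignment.

`motif_to_sequence` is the exact inverse of calling for motifs off the
exclusion set, with one caveat: indel placement inside homopolymer runs is
alignment-ambiguous for any aligner, so the round-trip guarantee is
asserted for substitution motifs (the synthetic generator's model) and for
indels in unambiguous contexts.

## Haplogroup assignment

A motif M is scored against every node h of a reduced haplogroup tree by
the Kulczynski similarity

    s(h) = ½ ( |M ∩ E_h| / |E_h| + |M ∩ E_h| / |M| ),

where E_h is the node's cumulative defining-variant set restricted to the
analysis window (back mutations along the path remove their ancestral
variant). Empty-set ratios are defined as 1, so the empty motif maps to the
root with score 1. Ties break toward the deeper node, then
lexicographically. This is a deliberate simplification of
fluctuation-weighted haplogroup callers: with a reduced tree and
near-complete motifs the unweighted score recovers the generating node
exactly (score 1) in the noiseless case and ≥95% of the time at 0.5
expected private mutations per sequence (measured in the test suite).

Relatedness control: samples from one burial site may be maternal kin, so
population analyses keep a single ancient record per (site, haplogroup) and
coalescence dating keeps a single record per site; the smallest sample id
survives (a deterministic, content-free tie-break) and modern records are
never deduplicated.

Mixed-granularity category schemas (a generic `H` next to `H1cf` and
`H4a1e`) are resolved by longest-prefix match, with slash buckets
(`L1/L2`) matching either prefix and `Other T`-style buckets absorbing the
remainder of their letter class at the lowest priority.

## Gene diversity

Nei's unbiased estimator and sampling variance:

    H  = n/(n−1) (1 − Σ pᵢ²)
    V  = 2/(n(n−1)) [ 2(n−2)(Σ pᵢ³ − (Σ pᵢ²)²) + Σ pᵢ² − (Σ pᵢ²)² ]

computed in double precision (exact to well beyond 10 significant digits
at these sample sizes). Diversity can be computed at haplotype or
haplogroup level; published island diversities are haplotype-level, and
only the El Hierro configuration (n = 70, counts 69/1) is reconstructible
from frequencies alone — it reproduces both the printed 2.86% and ±2.76%.

## Exact Fisher asymmetry tests

Each haplogroup category is tested against all others pooled in a 2×2
table (present/absent × east/west). The two-tailed p-value is the sum of
hypergeometric probabilities, over the full support of tables with the
observed margins, that do not exceed the observed table's probability; a
relative tolerance of 1e−7 absorbs floating-point ties. Terms are computed
with log-gamma, so N in the hundreds is exact to double precision. A zero
margin yields p = 1. This "sum of small tables" convention is the one under
which all printed p-values of the study system reproduce to four decimals.
The default partition places Gran Canaria and Lanzarote+Fuerteventura
(pooled) in the east; populations can be excluded to re-test without
drift-dominated outliers.

## Distances and ordination

Pairwise Φ_ST uses the two-population AMOVA with 0/1 inter-haplotype
distances, making it a pure frequency statistic:

    SSD_g = (n_g/2)(1 − Σ p_gi²),  SSD_T = (N/2)(1 − Σ P_i²)
    σ_w² = Σ_g SSD_g / (N−2),      σ_a² = (SSD_A − σ_w²)/n_c,
    n_c = N − (n₁²+n₂²)/N,         Φ_ST = σ_a²/(σ_a²+σ_w²)

Negative variance-component estimates are truncated to zero before
Slatkin's linearization D = Φ/(1−Φ), keeping the MDS input a
dissimilarity; Φ = 1 is capped at D = 1e6. A molecular-distance Φ_ST
variant is intentionally out of scope.

MDS is SMACOF: classical (Torgerson) scaling initializes the
configuration, the unweighted Guttman transform iterates, and iteration
stops when normalized stress-1, √(Σ(δ−d)²/Σδ²), decreases by less than
1e−6 (default; 1000 iterations max). Majorization makes raw stress
non-increasing, so the recorded stress-1 trajectory is monotone; the seed
matters only when the Torgerson start is degenerate (e.g. an all-zero
matrix). 2-embeddable inputs reach stress < 1e−8 immediately from the
Torgerson start.

## Admixture

Long's WLS: with hybrid frequency vector h and parental matrix P, minimize
(h − Pm)ᵀW(h − Pm) subject to Σm = 1 by substituting the last component
into the normal equations. W is diagonal with wᵢ = 1/(p̄ᵢ(1−p̄ᵢ)), p̄ the
unweighted mean of parental frequencies; categories with p̄ ∈ {0,1} carry
no information and are dropped. A condition-number guard (1e10) turns
collinear parentals into an explicit error. Components outside [0,1] are
clipped and renormalized — chosen over quadratic programming for
transparency; the box/simplex-constrained solve is available as
`mode="constrained"` and agrees on interior solutions. Uncertainties come
from multinomial resampling of the hybrid and every parental at their
observed sample sizes (default B = 1000, seeded); an analytic GLS
covariance is available as a cross-check since the original method's error
convention is not documented.

## Median-joining networks and ρ dating

Haplotypes are vectors over one column per occupied (position,
insert_index) site. The ε-relaxed minimum spanning network links u,v iff
d(u,v) ≤ merge-level(u,v) + ε, where the merge level is the distance
threshold at which the two first join one component when links are
admitted in ascending order — for ε = 0 this is exactly the union of all
minimum spanning trees. The construction then repeatedly adds
majority-consensus medians of each node and two of its network neighbours
(three-way column ties keep the centre node's state — a pinned
deterministic convention; nodes are processed in lexicographic motif
order) until no new median appears, and finally deletes unsampled medians
of degree ≤ 2, whose paths the remaining links already realize. ε defaults
to 0 and is exposed.

Two properties are guaranteed and tested: sampled haplotypes are never
deleted, and the shortest connected subgraph of the network spanning the
sampled nodes realizes the optimal Steiner-tree length (verified against
exhaustive Steiner-point enumeration for small inputs), hence never
exceeds an MST of the input. The network itself may contain reticulations
and so can have total edge length above MST length — that redundancy is
the point of the method, displaying alternative equally parsimonious
connections. On the 3-column hypercube the node set also matches the union
of all optimal Steiner trees' junction nodes exhaustively; beyond three
columns the greedy ε = 0 construction can both add and miss medians
relative to that union, which is the known reason the ε parameter exists.

For dating, the network is rooted at a designated ancestral motif
(attached as an unsampled node if it is within one mutation of the
network), reticulations are resolved by a breadth-first shortest-path tree
with ties broken toward the lexicographically smaller parent, and

    ρ = (1/n) Σ_samples d(sample, root),
    σ² = (1/n²) Σ_links l_link · n_link²

with n_link the number of sampled sequences below a link. Ages are
ρ × 3,624 years — the whole-mitogenome substitution rate corrected for
purifying selection — with SE σ × 3,624. ρ is computed in exact rational
arithmetic before conversion. Clades with fewer than two distinct
haplotypes return ρ = 0 flagged low-information rather than erroring.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:

- **Island populations** are multinomial draws from fixed haplogroup
  frequency vectors; the bundled default mirrors the six ancient island
  samples of the study system (n = 70, 35, 53, 57, 87, 20; 19 categories).
- **Sequences** realize each sample's haplogroup motif plus
  Poisson-distributed private substitutions (default mean 0.5 per
  sequence, a realistic HVRI private-variant load; rate 0 gives exact
  recovery). Private mutations avoid excluded positions so round trips are
  exact.
- **Admixed populations** are multinomial draws from a known convex
  combination of parental frequency vectors.
- **Genealogies** are star or random ultrametric bifurcating (yule)
  topologies in which every root-leaf path spans the true age and each
  branch accumulates Poisson(length/rate) mutations at fresh positions
  along its path.

Not emulated: post-mortem DNA damage and contamination, sequencing error,
heteroplasmy, within-island site structure (each synthetic sample gets its
own site, so deduplication is exercised separately), recombination (absent
in mtDNA), and back mutation in simulated genealogies. Passing tests
therefore certify the statistical machinery, not robustness to aDNA
artefacts — those belong to the upstream read-processing and
authentication stages, which are out of scope here.

The reduced haplogroup tree and the HVRI reference segment bundled for
testing are synthetic (marked as such): the tree's defining variants are
loosely modelled on classic control-region motifs, and the reference is a
deterministic random segment adjusted so every tree variant is a real
change against it.

## Problem sizes and test design

The test suite validates each statistic against an independent oracle:
exact rational enumeration for Fisher (1,000 random tables), explicit
pairwise-distance AMOVA (200 random population pairs), exhaustive
Steiner-point enumeration for networks (all 3-column inputs of 2–5
haplotypes plus random 4–6-column inputs), a Lagrange-multiplier
least-squares oracle for admixture, and closed forms for ρ/σ. Parameter
recovery uses 200 multinomial replicates (n = 300) for admixture and 100
star genealogies of 200 lineages at a true age of one clock unit for
dating; these sizes give Monte-Carlo standard errors comfortably below the
asserted tolerances while keeping the suite quick.

## Known limitations

- Haplogroup assignment is unweighted; on the full phylotree with sparse
  HVRI motifs a fluctuation-weighted scheme would discriminate better.
- The admixture clip-and-renormalize step biases boundary estimates
  slightly toward the interior; use `mode="constrained"` when proportions
  are expected to sit at 0.
- ρ dating inherits the known fragility of the statistic on strongly
  non-star genealogies; the Saillard σ understates uncertainty there.
- The Fisher scan reports raw p-values (as the study system did); no
  multiple-testing correction is applied.
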