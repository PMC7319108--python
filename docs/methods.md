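# Methods

This note documents the models, estimators and numerical choices behind
`plastpop`, and what its synthetic data can and cannot establish.

## Scope and data model

Every analysis consumes a gapped multiple sequence alignment (`AlignedSet`)
with optional sample → population → group labels. Alignment inference itself
is out of scope: insertions in simulated data are realized directly as gap
columns in non-carrier samples, so simulated alignments are exact by
construction, and real alignments are accepted as produced by an external
aligner. All reported coordinates are 1-based closed intervals over alignment
columns; TSV outputs carry `#`-comment headers with the tool version,
parameters and seed (never timestamps, so fixed-seed runs are byte-identical).

Characters outside `{A,C,G,T,-}` are ambiguous; `trim_alignment` removes any
column containing one in any sequence and reports the retained original
coordinates.

## Plastome scan

The trimmed alignment is tiled into bins of `bin_length` columns (default
400 bp; the final bin may be short and is retained, so per-bin counts
partition the alignment-wide totals exactly). Per bin:

- **snp_count** — segregating sites: columns with ≥ 2 distinct non-gap bases
  among the ingroup. Pairwise-vs-reference counting would be an alternative
  reading for three genomes; segregating sites is well defined for any *n*
  and is the convention used throughout.
- **indel_count** — distinct maximal gap runs. A run is one mutational event;
  runs with identical extent in several samples are one shared event, and a
  run carried by *every* sample is no event at all (no variation among the
  ingroup). Each event is credited to the single bin containing its leftmost
  column, which is what makes the conservation invariant exact.
- **gc** — G+C fraction over ingroup non-gap bases (NaN for all-gap bins).
- **ssr_count** — SSR loci (mapped from ungapped to alignment coordinates)
  whose leftmost column falls in the bin.

Hotspot ranking scores bins by `snp + indel`, ties broken by higher SNP count
then lower coordinate; adjacent selected bins fuse into one region and
selection continues until `k` regions exist (default 27, the scale used in
plastome marker screens) or variable bins are exhausted.

### cpSSR detection

`detect_ssrs` reports every maximal perfect tandem repeat with motif length
1–6 bp, requiring ≥ 8 units for mononucleotide motifs and ≥ 5 units
otherwise (the GMATo-style thresholds used for chloroplast SSR screens).
Loci are reported once at their smallest period (motifs that are themselves
periodic are skipped); overlapping candidates are resolved leftmost-longest.
Compound and imperfect SSRs are not modeled. Polymorphic-cpSSR screening
detects per-sample loci on ungapped sequences, maps them to alignment
columns, clusters loci with overlapping spans and identical canonical motif
rotation, and calls a cluster polymorphic when unit counts differ among
samples (a sample in which the locus falls below threshold contributes an
absent allele, reported as 0 units).

## Haplotypes and diversity

`collapse_haplotypes` builds a character matrix from the alignment:

1. terminal gaps are per-sample missing data (the sample does not vote),
   never indel events;
2. when enabled (default), columns inside mononucleotide runs ≥ 8 bp in any
   sample are masked — homopolymer length variation is slippage, scored
   separately as cpSSR variation (the cutoff is a parameter and deliberately
   matches the mono-SSR threshold);
3. every distinct maximal internal gap-run extent becomes one binary
   presence/absence character (an indel is a single mutation event,
   regardless of length);
4. remaining segregating columns are substitution characters.

A haplotype is a distinct joint state; ids `H1, H2, …` are assigned by
decreasing global count, ties by first occurrence after sample-id sort, which
makes numbering reproducible under input reordering. Distances are counts of
differing characters (missing states do not contribute); nucleotide diversity
uses the substitution characters only, over `L_effective` — the unmasked
columns with no gaps or missing data in any sample.

Diversity estimators: `Hd = n/(n-1)(1 - Σ p_i²)` and
`Pi = n/(n-1) Σ_{i<j} 2 p_i p_j d_ij / L`.

## Differentiation

The Pons–Petit family is implemented with unweighted population means and a
harmonic-mean total correction: per-population `h_k = n_k/(n_k-1)(1-Σp²)`,
`Hs = mean(h_k)`, `Ht = 1 - Σ p̄² + Hs/(ñP)`; the ordered analogs replace
`1-Σp²` by `Σ_{i≠j} p_i p_j d_ij` with the same corrections. The identity
`Nst = Gst` under equal inter-haplotype distances is the correctness anchor
and is asserted to machine precision. Note a consequence of the unbiased
corrections: literally duplicating one sample as two "populations" yields a
slightly *negative* Gst, not zero — the estimators are unbiased over
sampling, not over copies. Populations with fewer than two samples are
excluded with a warning. The phylogeographic-structure test permutes
haplotype identities on the distance matrix (frequencies fixed), with
`p = (1 + hits)/(n_perm + 1)` so p-values are never zero.

AMOVA follows the squared-distance decomposition: `SSD` terms from
`(1/n) Σ_{i<j} δ²`, variance components by the method of moments with the
standard unequal-size coefficients, Φ indices from component ratios, and
negative components reported as computed (percentages use the raw values).
`δ²` is the squared haplotype step count by default; a flag substitutes raw
steps for sensitivity analysis. Permutation schemes: samples among
populations for Φst, samples among populations within groups for Φsc, whole
populations among groups for Φct. A grouped design with a single group falls
back to the one-level decomposition exactly. The test suite validates the
components against an independent expected-mean-squares solver that derives
its coefficients from projection-matrix traces and the Gower-centered `δ²`
matrix rather than the closed-form sample-size formulas.

## Median-joining networks

The minimum spanning network is the union of all minimum spanning trees: an
edge belongs to it iff its weight does not exceed the minimax (bottleneck)
distance between its endpoints, plus an `epsilon` relaxation (default 0, as
in common practice). Median generation iterates over triplets connected in
the current MSN, forms the per-character majority consensus (a three-way tie
falls back to the state of the first node in canonical order), adds the
median that most reduces the minimum-spanning cost, and repeats to fixpoint
(capped at 10,000 additions). Median vectors not on any shortest path between
observed haplotypes are finally removed, so surviving medians have degree
≥ 2. Substitution and indel characters carry equal weight. The construction
is deterministic given the canonical node ordering.

## Haploid admixture clustering

A STRUCTURE-style mixture model for haploid genotypes: sample *i* has
admixture vector *Q*<sub>i</sub> over *K* clusters, cluster *k* has per-locus
allele frequencies *P*<sub>kl</sub>; the latent origin of each observed
allele is drawn from *Q*<sub>i</sub>, the allele from the origin's
frequencies. Gibbs sampling uses conjugate updates: `P | z ~
Dirichlet(λ + counts)` (independent frequencies, λ = 1; the hierarchical
correlated-frequency model is deliberately out of scope for six haploid
loci), `Q | z ~ Dirichlet(α₀ + origin counts)`, `z | P,Q` categorical.
Missing alleles (−9) are skipped. `lnPD = mean(lnL) − var(lnL)/2` over
post-burn-in sweeps, the usual model-choice estimator.

α₀ is fixed, not sampled. Its default is 0.1: with haploid data each sample
contributes at most *L* origin draws, so the posterior mean of a pure
sample's home proportion is capped at `(α₀+L)/(Kα₀+L)`; α₀ = 1 would cap
assignment near 0.92 for K = 2 with a 10-locus panel no matter how diverged
the clusters, while 0.1 admits near-pure membership and still allows genuine
admixture to be expressed. Desk-scale defaults are 5,000 burn-in / 20,000
sweeps; production-scale chains are available through the same flags.

A practical note on model choice: fitting K+1 clusters to unstructured data
always gains a little raw lnPD (mild overfitting), which is precisely why
`evanno_delta_k` — `ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))`, sample sd
over replicate runs, undefined at boundary K or zero sd — is used for
selecting K rather than lnPD itself. Replicate runs are label-aligned by
minimum-cost column assignment before averaging.

## Synthetic data

`simulate_reference_plastome` draws bases independently with region-specific
GC (background default 0.37, the AT-rich composition typical of these
genomes), overrides hotspot intervals with their local (AT-biased) GC,
writes declared SSR seeds verbatim, and mirrors the first IR as the second's
reverse complement. Hotspots may not overlap the second IR copy (the mirror
would overwrite them); place them in LSC, IRa or SSC.

`simulate_population_alignment` builds a haplotype pool by a two-tier star
process: deme founders radiate independently from the ancestral reference
with `Poisson(divergence_steps)` mutations (at least one, so pool haplotypes
are sequence-distinct), and the remaining pool haplotypes derive from their
deme's founder with `Poisson(within_deme_steps)` further private steps
(default 1). The two tiers matter: they make within-deme haplotypes more
similar than between-deme ones, which is what gives Nst > Gst and is the
pattern real isolated demes show; a single-tier star would make all
haplotypes exchangeable. Mutation *positions* are drawn proportionally to
per-site rates — the hotspot's own rate inside hotspot intervals, one tenth
of the maximum hotspot rate elsewhere — and the *number* of mutations is set
by the divergence parameters; with all rates zero no mutations occur.
Mutation types at a site follow the relative SNP/indel rates; indels are
1–10-column events (small indels dominate intraspecific plastome variation),
realized as deletions in the carrier or insertions (gap columns in everyone
else). Each seeded SSR locus gets 0–3 extra repeat units per pool haplotype,
padded with gaps to a common block width. Admixture `m` makes each sample
draw its haplotype from a uniformly chosen other deme with probability `m`.
Default demography (five demes of 9/7/2/6/4 samples, pool of 11 haplotypes,
divergence 5 steps) mirrors the sampling design of the motivating study.

`simulate_cpssr_genotypes` draws per-cluster, per-locus allele frequencies
from a symmetric Dirichlet (`divergence` concentration; small values give
strongly diverged clusters), or fully diverged fixed-alternate alleles on
request; `admixture_alpha = 0` gives pure membership, larger values spread
`Q_i ~ Dirichlet(α·1 + e_home)`.

What the generator does *not* emulate: coalescent genealogies with
recombination, selection, heteroplasmy, alignment error, sequencing error,
or compound/imperfect SSRs. Tests passing on these simulations establish the
estimators' correctness and the pipeline's sensitivity under clean, known
truth — not performance on noisy real assemblies.

## Problem sizes and determinism

The packaged demo plastome is a 12 kb quadripartite miniature (LSC 6,000 /
IR 2,400 / SSC 1,200) with four hotspot intervals; simulation-based tests use
20 replicates for Monte-Carlo sign and recovery properties and 10 seeds for
sampler recovery, with Gibbs chains of 2,000 burn-in / 10,000 sweeps for
recovery checks and shorter chains for smoke tests — sizes chosen so the
whole suite runs on a laptop. Every stochastic routine takes an explicit
seed (`numpy.random.default_rng`); permutation p-values use the
`(1 + hits)/(1 + n_perm)` convention; ties in hotspot ranking, median
generation and label alignment are broken by documented canonical orderings,
so all outputs are bit-reproducible for fixed seed and inputs.

## Known limitations

- Pairwise-deletion handling of missing states in haplotype distances can
  understate distances for heavily end-trimmed samples.
- The Pons–Petit total-diversity estimator and the pooled-sample Hd are
  different statistics and will differ on the same data; both are reported.
- The median-joining implementation targets small haplotype sets (tens of
  haplotypes); its exhaustive triplet scan is quadratic-to-cubic in nodes.
- The admixture sampler fixes α₀ and λ; no LOCPRIOR, linkage model, or
  correlated allele frequencies.
- AMOVA is limited to the two hierarchical levels (groups / populations);
  no ordered-allele Rst for cpSSRs.
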