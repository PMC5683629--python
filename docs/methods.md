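# Methods

This note documents the models and procedures implemented in `barcodeaudit`,
the assumptions behind them, the tunable parameters, the numerical choices,
and what the synthetic-data tests do and do not establish about real data.

## Distances

All delimitation operates on uncorrected p-distances: the fraction of
mismatching sites among alignment columns where both sequences carry an
unambiguous base (A/C/G/T). Columns with a gap or N in either sequence are
excluded per pair (*pairwise deletion*), so the number of compared sites
varies across pairs; it is recorded alongside each distance. No
substitution-model correction is applied — threshold conventions in the
barcoding literature (2.2% BIN proxy, 3% 16S conspecificity, ABGD priors)
are quoted on the uncorrected scale, and applying them to corrected
distances would shift every boundary.

Ambiguity handling: on read, sequences are upper-cased, U→T, and every IUPAC
code other than N is collapsed to N. Pairwise deletion treats all ambiguity
identically, so finer codes carry no information for these methods.

`min_overlap` (default **100 sites**) guards against fragmentary sequences:
any pair sharing fewer comparable sites fails loudly, listing the offending
pairs so the caller can drop specimens and retry. Real COI barcodes run
~500–660 bp and 16S ~490–580 bp, so 100 rejects only degenerate fragments.

## Delimitation

**Fixed-threshold clustering (BIN proxy).** Single-linkage connected
components of the graph with edges where d ≤ t, default **t = 0.022**. This
stands in for BOLD's proprietary BIN algorithm, which cannot be run offline;
the fixed 2.2% difference is the standard shorthand for it. Single linkage
is deliberate: it reproduces the chaining behaviour of haplotype clusters
(a ≤ t-chain of intermediates merges endpoints farther than t apart).

**Automatic Barcode Gap Discovery.** For each prior P on the geometric grid
P_k = Pmin·(Pmax/Pmin)^(k/(steps−1)) (defaults **Pmin = 0.001, Pmax = 0.1,
steps = 10, X = 1.5, Nb = 20**): sort all pairwise distances ascending; find
the first index i with d₍ᵢ₊₁₎ > P whose jump d₍ᵢ₊₁₎ − d₍ᵢ₎ exceeds X times
the mean consecutive-gap width over a window of w = max(3, ⌈N/Nb⌉)
distances ending at i; split by single linkage at the gap midpoint
(d₍ᵢ₎ + d₍ᵢ₊₁₎)/2; recurse within each group until no further gap
qualifies. The reported partition is the recursive partition whose group
count is stable over the longest run of consecutive priors, ties resolved
toward smaller priors.

*Known limitation.* At the smallest priors the recursion shatters species
into haplotype groups (authentic gap-discovery behaviour). When within-species
divergence approaches ~1%, that shattered plateau can persist over as many
consecutive priors as the true partition's plateau, and the
smaller-prior tie rule then selects the oversplit partition; the same
happens when clusters have only two members (a single intra-cluster
distance gives the spurious run maximal stability). With within-species
divergence ≲0.5%, or with ≥4 specimens per species, selection is reliable —
and in the full pipeline the 16S reconciliation stage re-merges oversplit
COI cells regardless (end-to-end recovery is exact at 1% intraspecific
divergence across 50 seeded communities). Single-locus users should read
the per-prior summary, not just the selected partition.

**Neighbor joining.** Classic agglomerative NJ on the Q criterion,
hand-implemented for determinism: ties are broken toward the
lexicographically smallest pair of node names (a node is named by the
smallest tip id beneath it), and negative branch-length estimates are
clamped to zero. On additive matrices NJ reproduces the generating tree
exactly (tested to n = 8, against path-length oracles and scikit-bio's NJ).
Trees are returned as dendropy objects; midpoint rooting and newick IO use
dendropy.

**16S conspecificity.** The deterministic default treats 16S clades as
single-linkage clusters at **t16 = 0.03**; published practice delimits 16S
clades by eye on NJ trees, which is not computable, and 3% is a conventional
16S congener boundary. A `monophyly` mode is provided for label-rich
datasets: maximal clades of the midpoint-rooted NJ tree containing at most
one distinct reference name.

## Reconciliation and naming

The two COI partitions are intersected into *cells* (the finest units either
method supports); a specimen lacking COI joins the unique cell whose members
share its 16S cluster, or is reported unassigned when its cluster spans
several cells. Pairs of cells are then evaluated:

| rule | 16S | locality | outcome |
|------|-----|----------|---------|
| R2 | same cluster | disjoint | merge (geographic variation) |
| R3 | same cluster | shared | merge (population variation) |
| R4 | different | shared | merge forbidden (sympatric lineages) |
| R5 | different | disjoint | merge only on a shared morphology flag |

OTUs are connected components of the merge graph. Transitive merge chains
that connect an R4-forbidden pair are cut by removing merge edges incident
to the forbidden pair — R3 edges before R2 — and the pair is logged as a
conflict; this case never arises in the published material, so the
resolution order is this package's own choice (drop the weaker sympatric
evidence first). Every merge carries provenance (cell pair, rule, action)
and replaying the provenance reproduces the partition.

"Fits the morphological description" (R5) is an input flag supplied by the
analyst, never computed: morphological diagnosis is expert work outside the
pipeline.

Naming precedence per OTU: (a) majority reference name among member
reference specimens (ties → alphabetical, flagged `cf`); (b) a name adopted
from a reference sharing a 16S cluster with a member; (c) `Genus cf.
epithet` when the nearest named OTU lies within **d_cf = 0.05** minimum 16S
distance (tentative assignment to closely related named material); (d)
provisional `Genus sp. A/B/…` under the modal field genus, letters by order
of first member appearance. d_cf is configurable; 5% sits above conspecific
16S divergence but within the range of sister species.

## Concordance audit

A survey specimen is **correct** iff (a) its field label equals its OTU's
assigned name, or (b) its label and OTU correspond one-to-one within the
audited scope. If one OTU carries several field labels, *all* its members
are misidentified — the field partition failed on that cluster, whichever
label each individual drew. A label applied across two OTUs (lumping) voids
criterion (b) for both; members can still pass via name equality.
`percent_correct` is taken over scored specimens; specimens without a field
label or OTU are reported unscored.

The genus table counts distinct field morphospecies per *field* genus and
distinct OTUs per *corrected* genus (an OTU named to a different genus than
its members' field labels counts under the corrected one), per season and
combined, with a totals row. Field overestimation is
(field_total − barcode_total)/barcode_total × 100, reported to one decimal
(headline figures round to the nearest ten).

## Richness

Incidence is binary per (species × sampling event). Sample-based rarefaction
uses the exact hypergeometric form τ(h) = Σ_j [1 − C(m−Y_j, h)/C(m, h)];
the mean is oracle-exact (equals exhaustive enumeration over all C(m,h)
subsets, tested to m = 8). The reported variance is the unconditional
moment form

  Var(τ̂(h)) = Σ_j (1 − α_jh)² − τ̂(h)²/S̃,  α_jh = C(m−Y_j, h)/C(m, h),

with S̃ the Chao2 estimate. It is non-negative whenever S̃ ≥ S_obs
(Cauchy–Schwarz) and stays positive at h = m while undetected species
remain, so full-effort curves carry uncertainty — unlike the conditional
(subset) variance, which vanishes at h = m and would make equal-effort
comparisons degenerate. The form assumes exchangeable species detection
probabilities; under strong heterogeneity it is conservative (simulations
here: matches the true sampling variance closely in the homogeneous regime,
overestimates by ~2× under Uniform(0.1, 0.7) detectabilities).

Chao2: with k = (m−1)/m, estimate = S_obs + k·Q1²/(2Q2) when Q2 > 0, else
the bias-corrected S_obs + k·Q1(Q1−1)/2; the classic variance forms for each
branch; CI by the log-normal construction on T = estimate − S_obs
(R = exp(z·√ln(1 + var/T²)), CI = [S_obs + T/R, S_obs + T·R]). The analytic
variance agrees with a 500-replicate bootstrap over sampling events within
25% on generated data. Chao2 is a lower-bound estimator: its CI attains
roughly nominal coverage when detectabilities are homogeneous (measured
~80% at the 84% level), but under strong heterogeneity it sits below the
true richness and coverage drops — an estimator property, not an
implementation artifact.

Confidence level: all intervals default to **84%** two-sided
(z = 1.4051), because non-overlap of two independent 84% intervals
corresponds approximately to a two-sample test at P = 0.05; comparing 95%
intervals would be badly conservative. Curves are compared at the smaller of
the two efforts, h = min(m_a, m_b), making the comparison deterministic for
unequal sampling.

## Synthetic communities

The generator emulates a barcode-audited inventory: K species; per-species
COI (654 bp) and 16S (550 bp) centroids drawn by rejection sampling until
every inter-centroid p-distance reaches **d_min_inter = 0.08**; each
specimen's sequences mutated from its centroids by uniform per-site
substitution to a different base at rate mu_intra/2 per copy, so conspecific
specimens differ at ≈ **mu_intra = 0.01** of sites; specimens spread
uniformly over localities and sampling events (events map onto seasons);
a **15%** reference fraction carrying true names. Field error rates default
to **p_split = 0.2, p_lump = 0.05, p_wrong_genus = 0.1** — no quantitative
field-error rates are published for inventories of this kind, so these are
illustrative magnitudes producing the observed qualitative pattern (splitting
dominates, overestimation in the field direction). Everything is
reproducible from a single seed.

What the generator does **not** emulate: gene-tree discordance between loci
(both loci share the species structure by construction — no hybridization or
incomplete lineage sorting), rate variation among sites or lineages,
alignment error (sequences are generated aligned), geographically structured
intraspecific variation, and abundance structure beyond uniform assignment.
Passing the end-to-end recovery suites therefore shows the pipeline is
correct *given* a clean barcode gap and congruent loci; it does not show the
method resolves the hard biological cases the delimitation literature warns
about, which real studies handle by adding evidence, not by this algorithm.

## Degenerate inputs and tie-breaks

All-zero distance matrices yield one group (no gap exists). Partitions use
canonical labels: consecutive integers from 1 in order of first member
appearance, so equal partitions compare equal. NJ requires n ≥ 2; n = 2
splits the single edge evenly. Chao2 requires m ≥ 2 events; Q1 = 0 returns
S_obs with a degenerate interval. Rarefaction CIs are floored at 0. Report
files are written with sorted keys and fixed float formatting, so identical
inputs produce byte-identical outputs.
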