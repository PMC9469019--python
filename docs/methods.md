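# Methods

`kinflow` analyzes temporally replicated codominant microsatellite surveys
of dispersive metapopulations. This note documents the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Data model

Genotypes are unordered pairs of integer allele lengths (base pairs), one
pair per diploid individual and locus, stored sorted ascending; a missing
call drops both gene copies (no half-calls). Alleles are taken as scored —
no fragment-size binning or repeat-unit normalization is applied, because
the target surveys score sizes directly on a capillary sequencer and
reconcile bins manually. Populations carry a code, site name,
decimal-degree coordinates, a sampling date, and a sampling-time code
(1–4: two collections per year over two consecutive years). GenAlEx
codominant CSV is the genotype exchange format (missing = 0); a
two-row-per-individual STRUCTURE export (missing = −9) is provided for
interoperability; site metadata travels in a separate CSV keyed by
population code. All text I/O is UTF-8 with `.` as the decimal point.

Allele frequencies are computed per (population, locus) over non-missing
gene copies only; cells with no data are flagged, not fatal. Statistics
that need a reference gene pool (LOD scores, threshold simulation, error
injection) use frequencies pooled across the whole time slice — pooling
avoids biasing parentage against cross-population pairs, which are exactly
the events of interest.

## Diversity and rarefaction

Per locus: Na = number of alleles with positive frequency; Ne = 1/Σp²
(the effective number of alleles — the column is labeled "Ne" to match the
field's standard table layout); I = −Σp ln p; Ho = heterozygote fraction
among typed individuals; He = 1 − Σp² (plug-in estimator; the unbiased
2N/(2N−1) correction is available behind a flag but off by default to
match the common toolkit convention). A population's row is the
unweighted mean over loci; loci with no data in that population are
excluded from its mean with a log note. Group means are unweighted
arithmetic means across population rows, rounded only at report time.

Rarefied allelic richness standardizes unequal sample sizes: at a
subsample of g gene copies the expected number of distinct alleles per
locus is Σ_a [1 − C(N−N_a, g)/C(N, g)], where N is the total copy count
and N_a the count of allele a; combinations with N−N_a < g contribute 1.
The private-allele expectation for a focal group multiplies each allele's
focal-presence probability by the probability of absence from every other
group's independent g-subsample. The rarefaction unit is gene copies (the
CLI also accepts individuals and doubles them). Binomial-coefficient
ratios are evaluated with log-gamma differences so pooled groups of many
hundreds of copies cannot overflow; the test suite checks exact agreement
(1e-12) with brute-force subset enumeration on pools of ≤ 8 copies.

One subtlety: for groups with *identical* allele counts, the rarefied
private-allele expectation is positive for g < N — an allele can be drawn
in the focal subsample yet missed by chance in the others — and reaches 0
only at g = N. This is a property of the estimator, confirmed by
exhaustive enumeration, not a bug.

Loci are equally weighted everywhere; no locus is weighted by its sample
size.

## Distances, ordination, isolation by distance

Nei's standard distance uses the arithmetic-mean-of-J formulation:
J_X = Σp², J_Y = Σq², J_XY = Σpq are each averaged across the loci typed
in both populations, then I = J_XY/√(J_X J_Y) and D = −ln I. Pairs sharing
no alleles at any locus get D = +∞ and are flagged; they are excluded
from PCoA input (with an explicit error telling the user to cap or drop)
and dropped pairwise from the Mantel test, never silently capped.

PCoA is the classical Gower construction: B = −½ J D² J, eigendecomposed;
coordinates are eigenvectors scaled by √λ for positive eigenvalues;
negative eigenvalues are reported but excluded from percent-variance.

Geographic distances are haversine great circles on a sphere of mean
radius 6371.0088 km. The discrepancy from an ellipsoidal geodesic is
below 0.5%, irrelevant at the pipeline's hundreds-of-km scale.

The genetic–geographic association is tested with a two-sided Mantel
permutation test rather than a naive regression p-value, because distance
matrix entries are not independent. r is the Pearson correlation over the
n(n−1)/2 population pairs; the null permutes rows and columns of one
matrix jointly. For n small enough that n! fits in the permutation
budget, all permutations are enumerated exactly; otherwise random
permutations with a +1/+1 continuity correction are used. The default is
9999 permutations with a required seed; the suite verifies a ~5% type-I
error at α = 0.05 and approximate uniformity of null p-values.

## Parentage likelihood and assignment

For an offspring genotype o and candidate parent genotype g at one locus,
the transition probability is P(o | one parent = g, other parent drawn
from the gene pool): the candidate transmits each of its alleles with
probability ½, the other allele is drawn from the pooled frequencies, and
the observed offspring genotype is reached through a class-II error
channel in which each observed allele is, with probability e, replaced by
a random allele from the locus frequency distribution. The channel is
applied to the offspring's observation; because it preserves the allele
marginal and the independence of gene copies, unconditional (unrelated)
genotypes remain Hardy–Weinberg, which gives the denominator. The
multi-locus LOD sums log₁₀ ratios over loci typed in both individuals
(≥ 10 of 15 shared loci required by default). At e = 0 the model reduces
exactly to Mendelian transmission — one incompatible locus forces
LOD = −∞ — while any e > 0 keeps all scores finite; incompatible-locus
counts are reported alongside.

Assignment screens every individual of a time slice as offspring against
every other individual (any population, self excluded) as a candidate
single parent, and retains the best-LOD candidate if it reaches the
threshold; exact LOD ties break toward the lexicographically smaller
candidate id and are logged. Sex is ignored (unrecorded in the target
surveys) and polygamy is implicit: one individual may be the best parent
of many offspring. Inbreeding is not modeled. Populations with fewer than
10 individuals are excluded from the kinship stage (they remain in the
diversity and distance stages): small samples carry too little pedigree
information and would contribute noise-dominated assignment counts.

**Threshold calibration.** The null LOD distribution is simulated by
drawing unrelated multilocus genotypes from the pooled frequencies. The
per-pair null (the distribution of a single unrelated pair's LOD) is
available, but the quantity that controls errors in a slice-wide screen is
the *best* LOD among the n−1 unrelated candidates an offspring is tested
against, so the pipeline calibrates against that best-of-n null
(`n_candidates` = slice size − 1) at quantile 0.999. This keeps the
per-offspring false-assignment probability at the nominal 0.1% level —
a per-pair quantile would be exceeded by the best of several hundred
candidates in a large fraction of screens.

**Direction is not identifiable from a single slice.** The parent–offspring
likelihood ratio P(o,g)/(P(o)P(g)) is symmetric in the two individuals,
and a field sample mixes generations without recording them, so a sampled
parent is typically assigned its own child as its "parent". Roughly half
of retained pairs in a fully parent-sampled simulation are
direction-reversed in exactly this way; they still connect true
parent–offspring dyads (> 95% of retained pairs at default settings).
Consequences: cross-population assignment *counts* between a pair of
populations are reliable, but the directed edge set partially symmetrizes
when flow is asymmetric, and source/sink labels from in/out-degree should
be read as tendencies, not counts of oriented events. Recovery is
therefore validated over dyads (either orientation).

**Error-rate robustness.** The assignment is repeated over a grid of
assumed error rates (default 0.0001, 0.001, 0.01, 0.05; the primary rate
0.0001 feeds downstream). Markers are declared informative when every
pairwise Jaccard overlap of the retained pair sets reaches 0.8 — the
assignments are then essentially insensitive to the assumed rate.

## Migration matrices and networks

Each retained pair increments n[destination][origin], destination = the
offspring's population, origin = the parent's. Rates are the row-wise
multinomial MLE m[i][j] = n[i][j]/Σ_j n[i][j] with Wilson 95% intervals
per cell (cell vs rest as binomial); rows with no assignments are flagged
undefined. No correction for unsampled parents is applied — validation is
against simulator truth with known parent sampling, and the Wilson
interval's coverage of the realized migrant fraction is checked directly
(≥ 90% in seeded replicates).

The gene-flow network adds a directed, unweighted edge origin→destination
for every off-diagonal count ≥ 1; node degree is in + out over directed
edges, unnormalized. Edge betweenness is computed on the undirected,
unweighted projection (Brandes counts, ties split equally) and then used
as edge weights for the clustering network, mirroring the two-network
construction (presence/direction network; betweenness-weighted undirected
network). Clustering is agglomerative greedy modularity (CNM): starting
from singletons, repeatedly merge the community pair with the largest
gain in Newman modularity Q = Σ_c [W_c/W − (S_c/2W)²], taking the
partition of maximal Q along the merge path; ties break toward the
lexicographically smallest community-label pair (a community is labeled
by its smallest node), making the result fully deterministic. Components
are clustered independently; isolated nodes are singleton clusters; an
edgeless graph has Q defined as 0. On unweighted two-clique and
disconnected-clique families the greedy attains the exhaustively verified
optimum (Q = 0.5 for disconnected triangles, 5/14 for bridged triangles);
on *weighted* graphs the greedy can be suboptimal — it may merge a heavy
bridge edge first and never undo it — which is an inherent property of
the fast-greedy family, verified against exhaustive partition search and
documented rather than patched.

Sources and sinks: out > in → source, in > out → sink, equal → mixed;
per-site persistence across slices is reported. Key nodes are per-cluster
and global degree maxima (all ties listed) plus bridge nodes (endpoints
of inter-cluster edges). Migration distances are geodesic edge lengths,
summarized per slice and pooled with mean, median, quartiles, maximum,
and a Student-t 95% CI of the mean (undefined and flagged for a single
edge); a bootstrap CI is not provided.

## The synthetic-data generator

The simulator exists to validate the pipeline against known truth, and
its defaults mirror the target study design: 12 demes, 15 loci, up to 10
alleles per locus, 4 time slices, ~30 sampled offspring per deme.
Founding allele frequencies are one Dirichlet(α = 1) draw per locus
shared by all demes (recently connected metapopulation); drift then
differentiates demes of finite size. Generations are non-overlapping and
each sampling-time slice is one generation: every offspring born in deme
i draws *each of its two parents* independently from deme j with
probability M[i][j] (j = i is resident mating) and uniformly within the
deme, and each parent transmits one allele per locus Mendelianly.
Migration thus acts through parentage — an immigrant adult breeding where
it lands — which is the signal kinship inference detects, and it makes
the origin distribution of the single assigned parent equal to M, so the
pipeline's row-normalized rates estimate M without a mating-system
correction factor. The emitted sample mixes generations (a configurable
fraction of the parental cohort joins the offspring sample), as a field
collection does. Demes sit on a jittered km grid mapped to latitude and
longitude, so distance-decay migration kernels and migration-distance
summaries can be exercised; a per-slice migration scale emulates
seasonally varying flow. Genotyping noise (class-II mistyping, missing
calls) is injected only into the emitted dataset; the recorded truth
(full pedigree, every parent's origin deme, raw allele transmissions) is
never perturbed.

What it does not emulate: mutation (off by default — slices span few
generations; a stepwise model is intentionally out of scope), selection,
sex-specific behavior, inbreeding, overlapping generations, age
structure, or wind-field realism. Passing recovery tests therefore show
that the inference machinery is correct under its own model assumptions,
not that real surveys meet those assumptions.

## Numerical and reproducibility choices

* Binomial coefficients in rarefaction via log-gamma; exact integer
  enumeration only in oracles.
* LOD computation is table-driven per locus (genotype-pair likelihood
  matrices), so slice-wide screens are O(n² · loci) array lookups.
* All Monte-Carlo stages require a seed; the pipeline fans a single
  master seed out through a CRC-based per-stage scheme, and a rerun with
  the same configuration and seed is byte-identical (tested).
* Report CSVs are written with `%.10g` floats; the run-config JSON
  records the seed and a configuration hash (output location excluded
  from the hash).
* Default problem sizes in the validation suite (demes of 100–120 with
  50–60 sampled offspring, 20–100 replicates) were chosen to give stable
  Monte-Carlo estimates of the calibrated error rates while keeping the
  suite comfortably interactive.

## Known limitations

* Pairwise single-parent assignment, not joint sibship reconstruction:
  sibship information that could orient pairs and sharpen assignments is
  unused.
* Pair direction is unidentifiable within a slice (see above); directed
  summaries partially symmetrize under asymmetric flow.
* Migration rates are conditional on assignment (no unsampled-parent
  likelihood correction); with sparse parent sampling the counts shrink
  but the row proportions remain approximately unbiased under uniform
  sampling.
* The rarefied-richness column reported per population (`Ar`) depends on
  the chosen g; cross-study comparability requires agreeing on g.
* Greedy modularity on weighted graphs is a heuristic; exhaustive
  optimality is guaranteed only where tested (small unweighted families).
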