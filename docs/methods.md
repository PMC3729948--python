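# Methods

This note documents the models, statistics and design choices behind
`commphylo`, a package for analysing the phylogenetic structure of forest
tree communities sampled as plot-by-species stem counts on a dated regional
phylogeny.

## Data model and units

A `Phylogeny` is a rooted tree (polytomies retained — family-level backbone
trees are typically unresolved below family) with branch lengths in millions
of years (Myr). Branch lengths may be absent on input; the dating step fills
them in, and all metrics refuse undated trees. A `CommunityMatrix` holds
non-negative integer stem counts (plots × species) plus per-plot metadata
(forest type, stratum, plot area in m²). Species names are matched to tree
tips exactly after trimming and underscore/space normalization; unmatched
species are dropped with a logged count, mirroring the common situation
where a few census taxa are absent from the phylogeny. Overstorey (dbh ≥ 5
cm) and understorey strata are analysed as independent communities sharing
the phylogeny.

## Node dating (bladj)

`bladj_date` assigns ages to undated internal nodes by even interpolation.
Nodes named in the ages file are fixed; tips are fixed at age 0. An undated
node takes its age from the chain between its nearest dated ancestor and the
oldest dated node reachable beneath it without crossing another dated node
(ties broken toward the shortest chain, then by label): with k steps down to
the node and n steps in the whole chain, age = A − k·(A − D)/n. Branch
lengths are then recomputed as parent age minus child age, so the output is
always ultrametric and the procedure is idempotent on a fully dated tree.
Input branch lengths are ignored. The root must be constrained; a dated node
older than a dated ancestor is an error. Age units are Myr throughout; the
root age comes from the ages file and is never guessed.

## Rarefaction

All plot-level diversity is computed on samples rarefied to a common stem
count (default: the smallest plot total) to remove sample-size effects. A
rarefied plot is a multivariate-hypergeometric draw from its observed counts
(sampling individuals without replacement), so rarefied row sums equal the
target exactly and no absent species can appear. Because the paper-style
protocol rarefies but reported metrics are single numbers per plot, the
pipeline averages each metric over R independent rarefaction draws
(default R = 100 for alpha metrics, R = 10 for the null-model indices, both
configurable and recorded in output metadata).

## Alpha diversity

With C the phylogenetic correlation matrix (c_ij = shared root-to-MRCA
depth divided by tip depth on an ultrametric tree, generalized to
sharedDepth/√(depth_i·depth_j) otherwise) and D the cophenetic (patristic)
distance matrix:

* **PD** (Faith): sum of branch lengths of the minimal subtree spanning the
  plot's species, including the path to the root (rooted convention, so a
  single species contributes its tip depth; an unrooted option is exposed).
* **PSV** = 1 − mean off-diagonal c_ij over the plot's species.
* **PSR** = S × PSV.
* **PSE**: the published abundance-weighted form,
  PSE = Σ_{i≠j} M_i M_j (1 − c_ij) / (N²·(S−1)/S), which penalizes both
  phylogenetic clumping and abundance unevenness and equals PSV at equal
  abundances. A `pairs` variant — the abundance-weighted mean correlation
  over heterospecific individual pairs subtracted from 1, denominator
  N² − ΣM_i² — is exposed for users who want a pure relatedness measure
  that is insensitive to unevenness on a star phylogeny. The default was
  cross-checked against R picante to 1e-9.
* **MPD** = Σ_{i≠j} M_i M_j d_ij / Σ_{i≠j} M_i M_j over heterospecific
  pairs (an option includes conspecific zero-distance pairs, picante's
  abundance-weighted convention).
* **MNTD** = Σ_i M_i · min_{j≠i} d_ij / Σ_i M_i (distance of each
  individual to its nearest heterospecific relative).

Metrics undefined for monospecific plots are emitted as missing values with
a reason code, never silently as zero.

Plot wood density is the basal-area-weighted mean of species wood densities,
BA_s = Σ_stems π(dbh/2)²; species missing a density take their genus mean
(flagged `genus-mean` in the trait table; species with no measured congener
are an error). Only stems at or above the overstorey census threshold
(dbh ≥ 5 cm, configurable) enter the weighting, so the understorey stratum
has no wood-density value by default.

## Null model and NRI/NTI

The independent-swap null repeatedly proposes a uniformly random 2×2
submatrix of the plot×species presence matrix and swaps it when it is a
checkerboard. Rejected proposals count as steps, which keeps the chain
doubly stochastic: its stationary distribution is uniform over the
margin-preserving configurations (counting only realized swaps would
over-sample configurations rich in checkerboards). Row sums (plot richness)
and column sums (species occurrence frequency) are preserved exactly, and
abundance values travel with their presence cells.

The burn-in per null matrix is sized to the matrix rather than fixed: a
uniform proposal hits a checkerboard with probability ≈ 2f²(1−f)² at fill
fraction f, and the default attempt count targets ≈3 realized swaps per
presence cell (capped at 5·10⁶ attempts). A fixed small attempt count
leaves the nulls correlated with the observed matrix, which biases the
standardized effect sizes toward zero and destroys the uniformity of the
rank-p under neutrality; the adaptive default restores both (verified by
the calibration tests). The count is configurable and recorded in outputs.

For each plot, NRI = −(MPD − mean MPD_null)/sd MPD_null and
NTI = −(MNTD − mean MNTD_null)/sd MNTD_null against 999 null matrices by
default, each generated by an independently seeded fresh chain from the
observed matrix; both statistics are read off the same null stream. The sd
uses ddof = 1. Positive values indicate phylogenetic clustering
(environmental filtering), negative values overdispersion (competitive
exclusion). A two-sided rank p with add-one correction is reported, plus
the one-sided quantile used for calibration checks. Plots whose null sd is
zero (e.g. a species set invariant under swaps) are flagged undefined.

## Beta diversity

Unweighted UniFrac between two pooled communities is the branch length
leading to descendants of exactly one community divided by the branch
length leading to descendants of at least one. Branches ancestral to
neither community and the path above the MRCA of the pooled community are
excluded from both numerator and denominator. UniFrac matrices are computed
per plot or per forest type (pooled plots).

Clustering is UPGMA (average linkage) with merge heights equal to the
average between-cluster dissimilarity at the merge; ties are broken by
lexicographic label order so results are deterministic. Node support comes
from a jackknife: each of 100 replicates subsamples an equal number of
individuals per group without replacement (default: the smallest group
total — the jackknife unit is the individual, by analogy with UniFrac's
original sequence jackknife; the choice is an assumption since plot- or
species-level jackknifes are equally defensible), recomputes the UniFrac
matrix and its UPGMA tree, and a node's support is the fraction of
replicates containing the same label bipartition.

## Accumulation curves

Individual-based curves are computed per plot, per forest type (pooled) and
for the whole landscape. The species curve averages cumulative richness
over 50 random orderings of the individuals (with the exact hypergeometric
expectation E[S(m)] = Σ_s [1 − C(N−N_s, m)/C(N, m)] as a cross-check). The
PD curve uses the per-branch form E[PD(m)] = Σ_b L_b·[1 − C(N−N_b, m)/C(N,
m)], where N_b counts individuals descending from branch b, or resampling.
PSR has no closed-form rarefaction and is resampled (50 draws, matching the
species-curve protocol), with grids thinned to ≤ 100 points for large
pools; monospecific subsamples, where PSV is undefined, are dropped with a
count. Every curve reproduces the full-sample statistic exactly at m = N.

## Group comparisons

Forest types are compared response-by-response with one-way ANOVA followed
by unadjusted LSD pairwise t-tests on the pooled MSE (LSD is by definition
unadjusted). When a Brown–Forsythe test (Levene on deviations from group
medians) finds unequal variances, a log transform is attempted for positive
responses; if variances remain unequal the Kruskal–Wallis test (with tie
correction) is used instead, with pairwise Mann–Whitney U tests feeding the
letter display. The test chosen and any transformation are recorded per
response. Letters are assigned by insert-and-absorb: groups sharing a
letter do not differ at α = 0.05.

## Synthetic data generator

The generator emulates a successional forest-plot study: a 240-species
regional pool on a pure-birth (Yule) tree scaled to a 100-Myr root age
(the pool size is of the order of the ~240 taxa a regional census of this
kind yields; tropical angiosperm crown ages motivate the root age), 4
forest types × 5 plots × 2 strata, 60 overstorey and 100 understorey stems
per 500 m² plot with plot richness 20 and 25. Abundances are log-series
distributed (θ = 0.95, the classic tropical-tree abundance model) and
assigned independently of the phylogeny.

Assembly regimes:

* **filtering** (young secondary): a multidimensional niche — 3 independent
  Brownian-motion axes, each standardized across tips — and a per-plot
  optimum drawn at a random species' position; species are sampled without
  replacement with weight exp(−s·‖z − opt‖²/d), default s = 10. One axis is
  supported, but Brownian motion on a single axis produces convergent
  trait values in distant clades, which caps how clustered a trait-filtered
  community can be; three axes make trait proximity track phylogenetic
  proximity much more closely, which is also the biologically natural
  reading of a multivariate environmental filter.
* **repulsion** (old secondary): sequential draws rejecting candidates
  whose nearest phylogenetic distance to the accepted set falls below the
  q-th quantile of the pool's pairwise distances, q = s/(1+s), default
  s = 4 (q = 0.8). If no candidate qualifies the threshold is relaxed by
  10% with a warning.
* **neutral** (old growth, underplanted old growth): uniform draws.

At strength 0 both structured regimes reduce exactly to the neutral draw.
Wood densities carry Brownian phylogenetic signal mapped through a logistic
transform into (0.25, 1.25) g/cm³, with 20% of species-level values
withheld (where a congener exists) to exercise the genus-mean fallback.
Stem diameters are log-normal above the 5-cm census threshold in the
overstorey and uniform on (1, 5) cm in the understorey. The generator also
emits the undated topology plus a complete internal-node ages file, so the
bladj step can be exercised end to end and reconstructs the true tree.

What the generator does *not* emulate: spatial structure and dispersal
limitation, temporal dynamics, observation error in identification, and
real abundance–phylogeny correlations. Passing recovery tests therefore
demonstrates that the estimators detect the assembly signal they were built
for under a known model — not that any particular field system assembles
this way.

## Numerical choices and problem sizes

Ultrametricity is asserted to 1e-9 relative; oracle comparisons are at
1e-9–1e-10 absolute; the correlation matrix is accepted as positive
semidefinite down to eigenvalues of −1e-8. Monte-Carlo comparisons of
resampling estimators to closed forms use 3 standard errors plus a 0.02
absolute allowance, because near curve saturation the cumulative count is a
rare-deficit (heavily skewed) variable for which a plain normal band is
slightly anti-conservative even though the estimator is exactly unbiased.
Calibration and recovery experiments run at the study's design scale (100
neutral plots or 30 regime plots of 60 stems from the 240-species pool, 999
nulls); the test suite uses those sizes directly, and smaller pools for the
purely structural checks. UPGMA and letter-display ties are broken
lexicographically. All stochastic stages consume independently spawned
substreams of a single master seed and are byte-reproducible.

## Known limitations

* The swap null explores one connected component of the checkerboard-swap
  graph; matrices whose configuration space is disconnected under 2×2 swaps
  are sampled only within the observed component (a general property of
  swap-based nulls).
* PSE's two published readings differ for uneven abundances; the default
  follows picante, and analyses mixing the two variants are not comparable.
* The repulsion regime's quantile constraint can become infeasible at high
  richness; the automatic relaxation (with warning) means realized
  overdispersion saturates rather than growing without bound.
* UniFrac here is the unweighted (presence/absence) form only.
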